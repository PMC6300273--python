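"""Exception hierarchy for the bpgrs pipeline.

Every stage raises a subclass of :class:`BpgrsError` so the pipeline
driver can abort with the stage name while persisting partial logs.
"""


class BpgrsError(Exception):
    """Base class for all bpgrs errors."""


class PanelValidationError(BpgrsError):
    """The SNP panel table violates a structural invariant (duplicate
    rsids, unknown trait label, missing beta or allele)."""


class HarmonizationError(BpgrsError):
    """A panel variant cannot be aligned to the genotype matrix (allele
    mismatch in both orientations, or beta exactly zero)."""


class GenotypeError(BpgrsError):
    """Malformed genotype input (bad VCF record, duplicate variant id,
    dosage out of range)."""


class ScoreError(BpgrsError):
    """Score computation impossible (zero variance, too few distinct
    values for quartiles, missing panel variant)."""


class ModelError(BpgrsError):
    """A regression model cannot be fitted (no outcome variation, empty
    stratum, inestimable term)."""


class SeparationError(ModelError):
    """Perfect or quasi-perfect separation detected in a fitted model."""


class ConvergenceError(ModelError):
    """Optimizer failed to converge within the iteration cap."""


class SimulationError(BpgrsError):
    """Invalid simulation configuration or failed calibration."""


class ConfigError(BpgrsError):
    """Invalid run configuration."""


class PipelineError(BpgrsError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
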