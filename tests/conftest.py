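import numpy as np
import pandas as pd
import pytest

from bpgrs.genotypes import GenotypeMatrix
from bpgrs.models import CovariateDesign
from bpgrs.panel import Panel, VariantSpec, combined_beta
from bpgrs.simulate import SimulationConfig, simulate_cohort


def make_variant(rsid, beta, effect="A", other="G", traits=None, **kw):
    betas = {t: beta for t in (traits or ["SBP"])}
    return VariantSpec(
        rsid=rsid, chrom="1", pos=int(rsid.strip("rs") or 1) * 100,
        effect_allele=effect, other_allele=other,
        betas=betas, beta=combined_beta(betas), **kw,
    )


def make_panel(betas, **kw):
    return Panel([make_variant(f"rs{j + 1}", b, **kw) for j, b in enumerate(betas)])


def make_gm(dosage, panel=None, ids=None, variant_ids=None, allele_ref=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if variant_ids is None:
        variant_ids = panel.rsids if panel else [f"rs{j + 1}" for j in range(m)]
    if allele_ref is None:
        if panel is not None:
            allele_ref = {v.rsid: (v.effect_allele, v.other_allele) for v in panel}
        else:
            allele_ref = {v: ("A", "G") for v in variant_ids}
    return GenotypeMatrix(
        ids or [f"ind{i + 1}" for i in range(n)], list(variant_ids), dosage, allele_ref
    )


def make_design(grs_quartile, age_quartile=None, extra_cols=None, pheno=None):
    """Minimal CovariateDesign from raw quartile labels for model tests."""
    q = pd.Series(np.asarray(grs_quartile, int))
    aq = pd.Series(np.asarray(age_quartile, int)) if age_quartile is not None \
        else pd.Series(np.ones(len(q), int))
    frame = pd.DataFrame(index=q.index)
    for k in (2, 3, 4):
        frame[f"grs_q{k}"] = (q == k).astype(int)
        frame[f"age_q{k}"] = (aq == k).astype(int)
    for col in ("male", "smoking", "bmi_underweight", "bmi_overweight",
                "bmi_obese", "diabetes", "hyperlipidemia", "stroke", "pad"):
        frame[col] = 0
    for name, vals in (extra_cols or {}).items():
        frame[name] = np.asarray(vals)
    ph = pheno if pheno is not None else pd.DataFrame(index=frame.index)
    return CovariateDesign(frame=frame, pheno=ph, grs_quartile=q, age_quartile=aq)


@pytest.fixture(scope="session")
def small_cohort():
    """2,000-individual, 30-SNP cohort under the default operating point."""
    cfg = SimulationConfig(n_individuals=2000, n_snps=30, seed=11)
    gm, panel, pheno, truth = simulate_cohort(cfg)
    return gm, panel, pheno, truth
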