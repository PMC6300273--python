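"""End-to-end orchestration: panel -> QC -> scoring -> association ->
report, as a configured, logged, seeded run writing a reproducible run
directory."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, PipelineError
from .genotypes import (
    QCReport,
    apply_hwe_filter,
    filter_sample_callrate,
    filter_variant_missingness,
    read_dosage_tsv,
    read_vcf,
)
from .models import (
    anova_grs_by_vessels,
    encode_covariates,
    fit_logistic,
    fit_multinomial,
    interaction_test,
    pleiotropy_screen,
    results_frame,
    run_sensitivity,
)
from .panel import (
    apply_mac_filter,
    ld_prune,
    load_panel,
    orient_to_risk,
    resolve_proxies,
    subset_by_trait,
)
from .scores import compute_scores
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

SUBSETS = ("all", "no_hypertension", "no_prior_ami")


@dataclass
class RunConfig:
    """One pipeline run: either real inputs (panel/genotype/phenotype
    paths) or simulation mode, plus the QC thresholds and analysis
    options."""

    out_dir: str
    seed: int = 0
    # real-input mode
    panel_path: str | None = None
    vcf_path: str | None = None
    dosage_tsv_path: str | None = None
    pheno_path: str | None = None
    proxy_map_path: str | None = None
    # simulation mode
    simulate: bool = False
    sim: dict = field(default_factory=dict)
    # analysis options
    score: str = "u"                    # u | w | both (scored anyway; models use this)
    trait: str = "ALL"                  # ALL | SBP | DBP | PP
    subset: str = "all"
    drop_ambiguous: bool = False
    missing_policy: str = "mean"
    # thresholds
    mac_threshold: int = 20
    max_variant_missingness: float = 0.05
    min_sample_callrate: float = 0.95
    hwe_alpha: float = 1e-4
    ld_r2: float = 0.8

    def validate(self) -> None:
        real = self.panel_path is not None and (
            self.vcf_path is not None or self.dosage_tsv_path is not None
        ) and self.pheno_path is not None
        if self.simulate == real:
            raise ConfigError(
                "exactly one of simulation mode or complete real inputs "
                "(panel + genotypes + phenotypes) must be configured"
            )
        if self.score not in ("u", "w", "both"):
            raise ConfigError(f"score must be u|w|both, got {self.score!r}")
        if self.trait.upper() not in ("ALL", "SBP", "DBP", "PP"):
            raise ConfigError(f"unknown trait {self.trait!r}")
        if self.subset not in SUBSETS:
            raise ConfigError(f"subset must be one of {SUBSETS}")
        if not (0 <= self.max_variant_missingness <= 1
                and 0 <= self.min_sample_callrate <= 1
                and 0 <= self.hwe_alpha <= 1
                and 0 <= self.ld_r2 <= 1
                and self.mac_threshold >= 0):
            raise ConfigError("threshold out of valid range")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sim_config(cfg: RunConfig) -> SimulationConfig:
    sim = dict(cfg.sim)
    sim.setdefault("seed", cfg.seed)
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(sim) - known
    if unknown:
        raise ConfigError(f"unknown simulation key(s): {sorted(unknown)}")
    sc = SimulationConfig(**sim)
    if isinstance(sc.vessel_quartile_logor, dict):
        sc.vessel_quartile_logor = {
            int(k): tuple(v) for k, v in sc.vessel_quartile_logor.items()
        }
    return sc


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and persist every artifact.

    Stage order: load/simulate inputs -> proxy resolution -> genotype QC
    (variant missingness, sample call-rate, HWE) -> risk orientation ->
    MAC filter -> LD pruning -> scoring/quartiles -> association models
    (+ configured subset sensitivity) -> summary + provenance manifest.
    Any stage failure aborts with the stage name; logs written so far are
    kept.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    qc_total = QCReport()
    counts: dict[str, dict] = {}

    def _fail(exc: Exception):
        _write_qc(qc_total, out)
        raise PipelineError(stage, str(exc)) from exc

    try:
        stage = "inputs"
        if config.simulate:
            gm, panel, pheno, truth = simulate_cohort(_sim_config(config))
            truth.to_json(out / "ground_truth.json")
        else:
            panel = load_panel(config.panel_path)
            if config.vcf_path:
                gm = read_vcf(config.vcf_path)
            else:
                gm = read_dosage_tsv(config.dosage_tsv_path)
            pheno = pd.read_csv(config.pheno_path)
        counts["inputs"] = {
            "panel_n": panel.N, "individuals": gm.n_individuals,
            "genotyped_variants": gm.n_variants, "pheno_rows": len(pheno),
        }

        stage = "proxy_resolution"
        if config.proxy_map_path:
            proxy_map = pd.read_csv(config.proxy_map_path, sep="\t")
            panel = resolve_proxies(panel, proxy_map, gm.variant_ids)
        else:
            # variants absent from genotyping with no proxy map are dropped
            missing = [v for v in panel if v.rsid not in gm.variant_index]
            if missing:
                kept = [v for v in panel if v.rsid in gm.variant_index]
                newp = type(panel)(kept, list(panel.exclusions))
                for v in missing:
                    newp.log_exclusion(v.rsid, "not_genotyped", "", "proxy_resolution")
                panel = newp
        counts["proxy_resolution"] = {"panel_n": panel.N}

        stage = "genotype_qc"
        gm = gm.subset_variants([r for r in panel.rsids if r in gm.variant_index])
        gm, rep = filter_variant_missingness(gm, config.max_variant_missingness)
        qc_total = qc_total.merge(rep)
        gm, rep = filter_sample_callrate(gm, config.min_sample_callrate)
        qc_total = qc_total.merge(rep)
        gm, rep = apply_hwe_filter(gm, config.hwe_alpha)
        qc_total = qc_total.merge(rep)
        dropped = [v for v in panel if v.rsid not in gm.variant_index]
        if dropped:
            kept = [v for v in panel if v.rsid in gm.variant_index]
            newp = type(panel)(kept, list(panel.exclusions))
            for v in dropped:
                newp.log_exclusion(v.rsid, "failed_genotype_qc", "", "genotype_qc")
            panel = newp
        counts["genotype_qc"] = {
            "panel_n": panel.N, "individuals": gm.n_individuals,
        }

        stage = "orientation"
        panel, gm = orient_to_risk(panel, gm, drop_ambiguous=config.drop_ambiguous)

        stage = "mac_filter"
        panel = apply_mac_filter(panel, gm, config.mac_threshold)

        stage = "ld_prune"
        panel = ld_prune(panel, gm, config.ld_r2)
        if config.trait.upper() != "ALL":
            panel = subset_by_trait(panel, config.trait)
        counts["final_panel"] = {"panel_n": panel.N}
        panel.write_exclusion_log(out / "exclusions.tsv")

        stage = "scoring"
        scores = compute_scores(
            gm, panel, trait=config.trait.upper(), missing=config.missing_policy
        )
        scores.to_csv(out / "scores.csv")

        stage = "association"
        score_kind = "w" if config.score == "w" else "u"
        design = encode_covariates(pheno, scores, score=score_kind)
        results = []
        for adjusted in (False, True):
            results += fit_logistic(design.pheno["hypertension"], design,
                                    adjusted=adjusted, outcome_label="hypertension")
            results += fit_logistic(design.pheno["chd"], design,
                                    adjusted=adjusted, outcome_label="chd")
            results += fit_multinomial(design.pheno["vessels"], design,
                                       adjusted=adjusted, outcome_label="vessels")
        if config.subset != "all":
            sens = run_sensitivity(gm, panel, pheno, config.subset,
                                   score=score_kind, missing=config.missing_policy)
            results += sens["chd"] + sens["vessels"]

        anova_f, anova_p = anova_grs_by_vessels(
            scores,
            design.pheno["vessels"],
            score=score_kind,
        )
        lr, lr_df, lr_p = interaction_test(design.pheno["chd"], design,
                                           outcome_label="chd")
        pleio = pleiotropy_screen(
            scores,
            design.pheno[["diabetes", "smoking", "hyperlipidemia", "bmi"]],
            score=score_kind,
        )
        # pleiotropy screen requires scores aligned with the design rows
        stage = "report"
        frame = results_frame(results + pleio)
        frame.to_csv(out / "associations.tsv", sep="\t", index=False)
        (out / "associations.json").write_text(
            frame.to_json(orient="records", indent=2) + "\n"
        )
        emit_forest_table(results).to_csv(out / "forest.csv", index=False)
        _write_qc(qc_total, out)
        _write_summary(out, scores, design, anova_f, anova_p, lr, lr_df, lr_p, counts)
        manifest = {
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "bpgrs_version": __version__,
            "n_tests_performed": len(results) + len(pleio) + 2,
            "stage_counts": counts,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
        )
    except PipelineError:
        raise
    except Exception as exc:
        _fail(exc)
    return out


def _write_qc(qc: QCReport, out: Path) -> None:
    try:
        qc.write(out / "qc_report.tsv", out / "qc_report.json")
    except Exception:  # pragma: no cover - best-effort persistence on abort
        logger.exception("failed to persist QC report")


def _write_summary(out, scores, design, anova_f, anova_p, lr, lr_df, lr_p, counts):
    s = scores.summary()
    ph = design.pheno
    lines = [
        "bpgrs run summary",
        "=================",
        f"analysis n: {design.n} (complete-case; dropped {design.n_dropped})",
        f"panel variants scored: {s['panel_n']} (trait {s['trait']})",
        "",
        "scores (raw scale)",
        f"  uGRS median [IQR]: {s['uGRS']['median']:.1f} "
        f"[{s['uGRS']['iqr'][0]:.1f}, {s['uGRS']['iqr'][1]:.1f}]",
        f"  wGRS median [IQR]: {s['wGRS']['median']:.1f} "
        f"[{s['wGRS']['iqr'][0]:.1f}, {s['wGRS']['iqr'][1]:.1f}]",
        f"  uGRS quartile sizes: {s['quartile_u_counts']}",
        f"  wGRS quartile sizes: {s['quartile_w_counts']}",
        "",
        "outcome prevalences",
        f"  hypertension: {ph['hypertension'].mean() * 100:.1f}%",
        f"  significant CHD: {ph['chd'].mean() * 100:.1f}%",
        "  vessel distribution (0/1/2/3): "
        + "/".join(f"{(ph['vessels'] == k).mean() * 100:.1f}%" for k in range(4)),
        "",
        f"ANOVA of GRS across vessel strata: F = {anova_f:.3f}, p = {anova_p:.3g}",
        f"GRS x age interaction LRT: chi2({lr_df}) = {lr:.3f}, p = {lr_p:.3g}",
        "",
        "stage counts: " + json.dumps(counts, sort_keys=True),
    ]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")


def emit_forest_table(results) -> pd.DataFrame:
    """Forest-plot-ready table: per outcome/model/level, a reference row
    (quartile 1, OR 1.0, empty CI) followed by the quartile-term rows,
    ordered by outcome, model, level, quartile."""
    rows = []
    seen = set()
    quartile_terms = {"grs_q2": 2, "grs_q3": 3, "grs_q4": 4}
    for r in results:
        if r.term not in quartile_terms:
            continue
        key = (r.outcome, r.model, r.level)
        if key not in seen:
            seen.add(key)
            rows.append({
                "outcome": r.outcome, "model": r.model,
                "level": "" if r.level is None else r.level,
                "quartile": 1, "or": 1.0, "ci_low": "", "ci_high": "", "p": "",
            })
        rows.append({
            "outcome": r.outcome, "model": r.model,
            "level": "" if r.level is None else r.level,
            "quartile": quartile_terms[r.term],
            "or": r.or_, "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["outcome", "model", "level", "quartile"], kind="stable"
        ).reset_index(drop=True)
    return df
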