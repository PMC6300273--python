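"""Genetic risk score computation: unweighted and effect-size-weighted
scores, standardization and quartile assignment.

For individual ``i`` over an oriented panel of ``N`` SNPs with dosages
``s_ij`` and positive effect sizes ``beta_j``::

    uGRS_i = sum_j s_ij
    wGRS_i = (N / sum_j beta_j) * sum_j beta_j * s_ij

The weighted score is normalized by the average effect size so both scores
live on the risk-allele-count scale; both are afterwards standardized to
mean 0, SD 1 for modelling, and analyses use quartiles of the score with
the lowest quartile as reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ScoreError
from .genotypes import GenotypeMatrix
from .panel import Panel

MISSING_POLICIES = ("mean", "drop", "zero")


def _panel_dosage(gm: GenotypeMatrix, panel: Panel, missing: str) -> np.ndarray:
    """Dosage submatrix over panel variants with the missing-data policy
    applied: ``mean`` imputes each variant's observed mean dosage (2x allele
    frequency), ``zero`` imputes 0, ``drop`` leaves NaN so affected
    individuals score NaN."""
    if missing not in MISSING_POLICIES:
        raise ValueError(f"missing policy must be one of {MISSING_POLICIES}")
    absent = [v.rsid for v in panel if v.rsid not in gm.variant_index]
    if absent:
        raise ScoreError(f"panel variant(s) missing from genotypes: {absent[:5]}")
    if any(v.beta <= 0 for v in panel):
        raise ScoreError("panel not oriented: betas must all be positive")
    d = np.column_stack([gm.column(v.rsid) for v in panel]).astype(float)
    if missing == "mean":
        mask = np.isnan(d)
        if mask.any():
            col_mean = np.nanmean(np.where(mask, np.nan, d), axis=0)
            if np.isnan(col_mean).any():
                bad = [panel.rsids[j] for j in np.where(np.isnan(col_mean))[0]]
                raise ScoreError(f"variant(s) with no observed dosage: {bad[:5]}")
            d = np.where(mask, col_mean[None, :], d)
    elif missing == "zero":
        d = np.nan_to_num(d, nan=0.0)
    return d


def unweighted_grs(gm: GenotypeMatrix, panel: Panel, missing: str = "mean") -> np.ndarray:
    """Per-individual count of risk alleles over the oriented panel."""
    if panel.N == 0:
        raise ScoreError("empty panel")
    return _panel_dosage(gm, panel, missing).sum(axis=1)


def weighted_grs(gm: GenotypeMatrix, panel: Panel, missing: str = "mean") -> np.ndarray:
    """Effect-size-weighted risk allele count, normalized by the average
    effect size: ``(N / sum beta) * sum_j beta_j s_ij``."""
    if panel.N == 0:
        raise ScoreError("empty panel")
    betas = np.array([v.beta for v in panel], dtype=float)
    beta_sum = betas.sum()
    if beta_sum <= 0:
        raise ScoreError("sum of panel betas must be positive")
    d = _panel_dosage(gm, panel, missing)
    return (panel.N / beta_sum) * (d @ betas)


def standardize(scores: np.ndarray, name: str = "score") -> np.ndarray:
    """Center and scale to sample mean 0 and sample SD 1 (n-1 denominator)."""
    x = np.asarray(scores, dtype=float)
    if np.isfinite(x).sum() < 2:
        raise ScoreError(f"{name}: need >= 2 observed values to standardize")
    mu = np.nanmean(x)
    sd = np.nanstd(x, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ScoreError(f"{name}: zero variance, cannot standardize")
    return (x - mu) / sd


def quartile_assign(scores: np.ndarray) -> np.ndarray:
    """Quartile labels 1-4 (1 = lowest) by nearest-rank 25/50/75
    percentile cuts; tied values share a quartile, assigned to the lower
    interval.  Invariant under monotone transformations of the scores."""
    x = np.asarray(scores, dtype=float)
    if np.isnan(x).any():
        raise ScoreError("scores contain missing values; resolve before binning")
    if np.unique(x).size < 4:
        raise ScoreError("need >= 4 distinct score values for quartiles")
    srt = np.sort(x)
    n = x.size
    cuts = [srt[int(np.ceil(q * n)) - 1] for q in (0.25, 0.50, 0.75)]
    return (1 + (x > cuts[0]).astype(int) + (x > cuts[1]) + (x > cuts[2])).astype(int)


@dataclass
class ScoreSet:
    """Per-individual scores (raw and standardized) and quartile labels."""

    individual_ids: list[str]
    ugrs_raw: np.ndarray
    wgrs_raw: np.ndarray
    ugrs_std: np.ndarray
    wgrs_std: np.ndarray
    quartile_u: np.ndarray
    quartile_w: np.ndarray
    trait: str = "ALL"
    panel_n: int = 0

    def __post_init__(self):
        n = len(self.individual_ids)
        for attr in ("ugrs_raw", "wgrs_raw", "ugrs_std", "wgrs_std",
                     "quartile_u", "quartile_w"):
            if len(getattr(self, attr)) != n:
                raise ScoreError(f"ScoreSet field {attr} length mismatch")

    def quartiles(self, score: str = "u") -> np.ndarray:
        if score not in ("u", "w"):
            raise ValueError("score must be 'u' or 'w'")
        return self.quartile_u if score == "u" else self.quartile_w

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_ids,
                "uGRS_raw": self.ugrs_raw,
                "wGRS_raw": self.wgrs_raw,
                "uGRS_std": self.ugrs_std,
                "wGRS_std": self.wgrs_std,
                "quartile_u": self.quartile_u,
                "quartile_w": self.quartile_w,
                "trait": self.trait,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        """Cohort-style descriptives: medians/IQRs on the raw scale and
        quartile group sizes."""
        def med_iqr(x):
            return {
                "median": float(np.median(x)),
                "iqr": [float(np.percentile(x, 25)), float(np.percentile(x, 75))],
            }

        return {
            "n": len(self.individual_ids),
            "panel_n": self.panel_n,
            "trait": self.trait,
            "uGRS": med_iqr(self.ugrs_raw),
            "wGRS": med_iqr(self.wgrs_raw),
            "quartile_u_counts": np.bincount(self.quartile_u, minlength=5)[1:].tolist(),
            "quartile_w_counts": np.bincount(self.quartile_w, minlength=5)[1:].tolist(),
        }


def compute_scores(
    gm: GenotypeMatrix,
    panel: Panel,
    trait: str = "ALL",
    missing: str = "mean",
) -> ScoreSet:
    """Full scoring pass: both scores, standardization, quartiles.

    With ``missing='drop'`` individuals with any missing panel dosage are
    removed before standardization and binning.
    """
    u = unweighted_grs(gm, panel, missing)
    w = weighted_grs(gm, panel, missing)
    ids = list(gm.individual_ids)
    if missing == "drop":
        ok = np.isfinite(u) & np.isfinite(w)
        ids = [s for s, k in zip(ids, ok) if k]
        u, w = u[ok], w[ok]
    return ScoreSet(
        individual_ids=ids,
        ugrs_raw=u,
        wgrs_raw=w,
        ugrs_std=standardize(u, "uGRS"),
        wgrs_std=standardize(w, "wGRS"),
        quartile_u=quartile_assign(u),
        quartile_w=quartile_assign(w),
        trait=trait,
        panel_n=panel.N,
    )
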