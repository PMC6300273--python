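"""Genotype containers, VCF / dosage-matrix I/O, and cohort QC filters.

Dosages are stored as an individuals x variants float matrix in [0, 2]
(count of the per-variant reference-orientation allele, NaN = missing).
QC follows the usual chip-cohort order: variant missingness, sample
call-rate, then Hardy-Weinberg equilibrium on hard calls.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

from .errors import GenotypeError

#: Soft dosages are rounded to hard calls only within this distance of an
#: integer; anything farther is treated as missing for HWE purposes.
HARD_CALL_TOL = 0.1


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with missingness and allele
    bookkeeping.

    ``allele_ref[rsid]`` is the ``(counted_allele, other_allele)`` pair the
    dosage column counts, or ``None`` for inputs (plain dosage TSV) where
    the counted allele is the panel's effect allele by convention.
    ``hard_call`` optionally holds integer genotypes (NaN = missing).
    """

    individual_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray
    allele_ref: dict[str, tuple[str, str] | None]
    hard_call: np.ndarray | None = None

    def __post_init__(self):
        self.individual_ids = list(self.individual_ids)
        self.variant_ids = list(self.variant_ids)
        n, m = len(self.individual_ids), len(self.variant_ids)
        if self.dosage.shape != (n, m):
            raise GenotypeError(
                f"dosage shape {self.dosage.shape} != ({n}, {m})"
            )
        if len(set(self.individual_ids)) != n:
            raise GenotypeError("duplicate individual ids")
        if len(set(self.variant_ids)) != m:
            raise GenotypeError("duplicate variant ids")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < -1e-9) | (self.dosage > 2 + 1e-9)
        if bad.any():
            raise GenotypeError("dosage values outside [0, 2]")
        missing_ref = [v for v in self.variant_ids if v not in self.allele_ref]
        if missing_ref:
            raise GenotypeError(f"allele_ref missing for {missing_ref[:5]}")
        self._vindex = {v: j for j, v in enumerate(self.variant_ids)}

    # -- accessors ---------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def variant_index(self) -> dict[str, int]:
        return self._vindex

    def column(self, rsid: str) -> np.ndarray:
        return self.dosage[:, self._vindex[rsid]]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.individual_ids),
            list(self.variant_ids),
            self.dosage.copy(),
            dict(self.allele_ref),
            None if self.hard_call is None else self.hard_call.copy(),
        )

    # -- mutation used by harmonization -----------------------------------

    def flip_variant(self, rsid: str) -> None:
        """Recode the dosage column to count the opposite allele (s -> 2-s)."""
        j = self._vindex[rsid]
        self.dosage[:, j] = 2.0 - self.dosage[:, j]
        if self.hard_call is not None:
            self.hard_call[:, j] = 2.0 - self.hard_call[:, j]
        ref = self.allele_ref.get(rsid)
        if ref is not None:
            self.allele_ref[rsid] = (ref[1], ref[0])

    # -- subsetting --------------------------------------------------------

    def subset_variants(self, rsids: list[str]) -> "GenotypeMatrix":
        cols = [self._vindex[r] for r in rsids]
        return GenotypeMatrix(
            list(self.individual_ids),
            list(rsids),
            self.dosage[:, cols].copy(),
            {r: self.allele_ref[r] for r in rsids},
            None if self.hard_call is None else self.hard_call[:, cols].copy(),
        )

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.individual_ids)}
        rows = [idx[s] for s in ids]
        return GenotypeMatrix(
            list(ids),
            list(self.variant_ids),
            self.dosage[rows, :].copy(),
            dict(self.allele_ref),
            None if self.hard_call is None else self.hard_call[rows, :].copy(),
        )

    def hard_calls(self, tol: float = HARD_CALL_TOL) -> np.ndarray:
        """Integer genotypes as floats (NaN = missing).  Uses the stored
        hard-call matrix when available, else rounds dosages within ``tol``
        of an integer and masks the rest."""
        if self.hard_call is not None:
            return self.hard_call.astype(float)
        hc = np.round(self.dosage)
        with np.errstate(invalid="ignore"):
            hc[np.abs(self.dosage - hc) > tol] = np.nan
        return hc


# ---------------------------------------------------------------------------
# I/O


def read_vcf(path: str | Path, dosage_field: str = "DS") -> GenotypeMatrix:
    """Read a (optionally bgzipped) VCF of biallelic records into a
    :class:`GenotypeMatrix`.

    Dosage prefers the per-sample ``DS`` FORMAT field when present on a
    record, falling back to the GT hard call (ALT allele count).  The
    dosage counts the ALT allele; ``allele_ref = (ALT, REF)``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids: list[str] = []
    cols: list[np.ndarray] = []
    hcols: list[np.ndarray] = []
    allele_ref: dict[str, tuple[str, str] | None] = {}
    seen: set[str] = set()
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GenotypeError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={rec.ALT}); split or filter first"
            )
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        if vid in seen:
            raise GenotypeError(f"duplicate variant id {vid}")
        seen.add(vid)
        gt = rec.gt_types.astype(float)  # 0/1/2 ALT copies, 3 = missing
        gt[gt == 3] = np.nan
        ds = None
        try:
            raw = rec.format(dosage_field)
        except KeyError:
            raw = None
        if raw is not None:
            ds = raw[:, 0].astype(float)
            ds[~np.isfinite(ds)] = np.nan
            ds[ds < -0.5] = np.nan  # cyvcf2 missing sentinel
        ids.append(vid)
        cols.append(ds if ds is not None else gt.copy())
        hcols.append(gt)
        allele_ref[vid] = (rec.ALT[0], rec.REF)
    if not ids:
        raise GenotypeError(f"no usable records in {path}")
    return GenotypeMatrix(
        samples, ids, np.column_stack(cols), allele_ref, np.column_stack(hcols)
    )


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT (rounded dosage) and DS fields.

    Variants with ``allele_ref=None`` are written with placeholder alleles
    A (counted/ALT) and G (REF).  Coordinates are synthetic (sequential)
    unless encoded in the variant id as ``chrom:pos``.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.individual_ids),
    ]
    hc = gm.hard_calls()
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j, vid in enumerate(gm.variant_ids):
        ref_pair = gm.allele_ref.get(vid) or ("A", "G")
        alt, ref = ref_pair
        fields = []
        for i in range(gm.n_individuals):
            d = gm.dosage[i, j]
            h = hc[i, j]
            gt = gt_str.get(int(h), "./.") if np.isfinite(h) else "./."
            ds = f"{d:.4g}" if np.isfinite(d) else "."
            fields.append(f"{gt}:{ds}")
        lines.append(
            f"1\t{j + 1}\t{vid}\t{ref}\t{alt}\t.\t.\t.\tGT:DS\t" + "\t".join(fields)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_dosage_tsv(
    path: str | Path,
    alleles: dict[str, tuple[str, str]] | None = None,
) -> GenotypeMatrix:
    """Read a plain dosage matrix TSV (``individual_id`` column + one
    column per rsid).  ``alleles`` optionally supplies the counted/other
    allele pair per variant; without it the counted allele is taken to be
    the panel's effect allele by convention (``allele_ref=None``)."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if "individual_id" not in df.columns:
        raise GenotypeError("dosage TSV must have an 'individual_id' column")
    vids = [c for c in df.columns if c != "individual_id"]
    dosage = df[vids].to_numpy(dtype=float)
    allele_ref: dict[str, tuple[str, str] | None] = {
        v: (alleles.get(v) if alleles else None) for v in vids
    }
    return GenotypeMatrix(list(df["individual_id"]), vids, dosage, allele_ref)


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(gm.dosage, columns=gm.variant_ids)
    df.insert(0, "individual_id", gm.individual_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# QC report


@dataclass
class QCReport:
    """Per-variant and per-sample QC metrics plus the exclusions a filter
    made (``(id, rule, value)`` triples)."""

    variant_missingness: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    sample_callrate: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    hwe_p: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    excluded: list[tuple[str, str, float]] = field(default_factory=list)

    def excluded_ids(self) -> set[str]:
        return {e[0] for e in self.excluded}

    def merge(self, other: "QCReport") -> "QCReport":
        def _cat(a: pd.Series, b: pd.Series) -> pd.Series:
            if a.empty:
                return b
            if b.empty:
                return a
            return pd.concat([a, b[~b.index.isin(a.index)]])

        return QCReport(
            _cat(self.variant_missingness, other.variant_missingness),
            _cat(self.sample_callrate, other.sample_callrate),
            _cat(self.hwe_p, other.hwe_p),
            self.excluded + other.excluded,
        )

    def exclusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.excluded, columns=["id", "rule", "value"])

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.exclusion_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            summary = {
                "n_excluded": len(self.excluded),
                "rules": sorted({e[1] for e in self.excluded}),
                "variant_missingness_max": (
                    float(self.variant_missingness.max())
                    if not self.variant_missingness.empty else None
                ),
                "sample_callrate_min": (
                    float(self.sample_callrate.min())
                    if not self.sample_callrate.empty else None
                ),
                "hwe_p_min": float(self.hwe_p.min()) if not self.hwe_p.empty else None,
            }
            Path(json_path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Filters


def filter_variant_missingness(
    gm: GenotypeMatrix, max_missing: float = 0.05
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop variants whose missing fraction exceeds ``max_missing``
    (strict ``>``, so a variant at exactly the threshold is retained)."""
    frac = np.isnan(gm.dosage).mean(axis=0)
    miss = pd.Series(frac, index=gm.variant_ids)
    report = QCReport(variant_missingness=miss)
    keep = [v for v, f in zip(gm.variant_ids, frac) if f <= max_missing]
    for v, f in zip(gm.variant_ids, frac):
        if f > max_missing:
            report.excluded.append((v, f"missingness_gt_{max_missing}", float(f)))
    return gm.subset_variants(keep), report


def filter_sample_callrate(
    gm: GenotypeMatrix, min_callrate: float = 0.95
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples whose call rate (non-missing fraction) is strictly
    below ``min_callrate``."""
    rate = 1.0 - np.isnan(gm.dosage).mean(axis=1)
    cr = pd.Series(rate, index=gm.individual_ids)
    report = QCReport(sample_callrate=cr)
    keep = [s for s, r in zip(gm.individual_ids, rate) if r >= min_callrate]
    for s, r in zip(gm.individual_ids, rate):
        if r < min_callrate:
            report.excluded.append((s, f"callrate_lt_{min_callrate}", float(r)))
    return gm.subset_individuals(keep), report


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium


def hwe_test(
    counts: tuple[int, int, int], method: str = "chisq", midp: bool = False
) -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts
    ``(n_AA, n_Aa, n_aa)``.

    ``method='chisq'`` (default): 1-df chi-square goodness of fit of the
    observed counts against p^2 : 2pq : q^2 at the observed allele
    frequency, no continuity correction.  ``method='exact'``: the exact
    conditional test, summing the probabilities of all heterozygote counts
    no more probable than the observed one at fixed allele counts
    (``midp=True`` subtracts half the observed outcome's probability).

    A monomorphic variant has no HWE departure to test; returns 1.0 with a
    warning.
    """
    n_aa_, n_ab, n_bb = (int(c) for c in counts)
    if min(n_aa_, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_ + n_ab + n_bb
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_a = 2 * n_aa_ + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        warnings.warn("monomorphic variant: HWE p defined as 1.0", stacklevel=2)
        return 1.0
    if method == "chisq":
        p = n_a / (2.0 * n)
        q = 1.0 - p
        expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
        observed = np.array([n_aa_, n_ab, n_bb], dtype=float)
        stat = float(((observed - expected) ** 2 / expected).sum())
        return float(chi2.sf(stat, df=1))
    if method == "exact":
        return _hwe_exact(n, n_a, n_ab, midp=midp)
    raise ValueError(f"unknown method {method!r}")


def _hwe_exact(n: int, n_a: int, het_obs: int, midp: bool = False) -> float:
    """Exact HWE test: enumerate heterozygote counts with the observed
    allele counts and sum probabilities <= that of the observed count."""
    n_b = 2 * n - n_a
    k_max = min(n_a, n_b)
    ks = np.arange(k_max % 2, k_max + 1, 2)  # parity of n_a is shared with het
    logp = (
        ks * np.log(2.0)
        + gammaln(n + 1)
        - gammaln((n_a - ks) / 2 + 1)
        - gammaln(ks + 1)
        - gammaln((n_b - ks) / 2 + 1)
    )
    logp -= logsumexp(logp)
    probs = np.exp(logp)
    p_obs = probs[np.where(ks == het_obs)[0][0]]
    total = probs[probs <= p_obs * (1 + 1e-12)].sum()
    if midp:
        total -= 0.5 * p_obs
    return float(min(1.0, total))


def genotype_counts(gm: GenotypeMatrix, tol: float = HARD_CALL_TOL) -> pd.DataFrame:
    """Hard-call genotype counts per variant, columns ``n0 n1 n2`` counting
    copies of the dosage-counted allele."""
    hc = gm.hard_calls(tol)
    rows = {}
    for j, v in enumerate(gm.variant_ids):
        col = hc[:, j]
        obs = col[np.isfinite(col)]
        rows[v] = [int((obs == g).sum()) for g in (0, 1, 2)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=["n0", "n1", "n2"])


def apply_hwe_filter(
    gm: GenotypeMatrix, alpha: float = 1e-4, method: str = "chisq"
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop variants failing Hardy-Weinberg equilibrium at ``p < alpha``
    (default 1e-4), on hard calls.  ``alpha=0`` disables the filter."""
    counts = genotype_counts(gm)
    pvals = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # monomorphic warning per variant
        for v, row in counts.iterrows():
            # counts are in copies of the counted allele; HWE is symmetric
            pvals[v] = hwe_test((row["n2"], row["n1"], row["n0"]), method=method)
    hwe = pd.Series(pvals)
    report = QCReport(hwe_p=hwe)
    keep = [v for v in gm.variant_ids if not pvals[v] < alpha]
    for v in gm.variant_ids:
        if pvals[v] < alpha:
            report.excluded.append((v, f"hwe_p_lt_{alpha}", float(pvals[v])))
    return gm.subset_variants(keep), report
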