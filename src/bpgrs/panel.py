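"""Blood-pressure SNP panel: loading, validation, filtering, risk orientation.

The panel is the set of GWAS-significant blood-pressure variants (systolic,
diastolic and/or pulse pressure) whose risk-allele dosages are summed into
the genetic risk scores.  Every exclusion a filter makes is recorded in an
append-only provenance log so the panel's attrition (initial panel -> MAC
filter -> proxy resolution -> LD pruning -> final score panel) can be
reconstructed from any run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import HarmonizationError, PanelValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .genotypes import GenotypeMatrix

#: Valid blood-pressure traits a panel SNP may belong to.
TRAITS = ("SBP", "DBP", "PP")

#: Columns required in a panel TSV.
PANEL_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "beta_sbp", "beta_dbp", "beta_pp", "traits",
]

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class VariantSpec:
    """One panel SNP with its per-trait effect sizes.

    ``betas`` maps each trait the SNP reached genome-wide significance for
    to its effect size in mmHg per effect allele; ``beta`` is the combined
    (single-score) weight, by default the trait beta of largest magnitude.
    After :func:`orient_to_risk` all betas are strictly positive.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    betas: Mapping[str, float]
    beta: float
    proxy_of: str | None = None
    proxy_r2: float | None = None

    def __post_init__(self):
        if self.effect_allele == self.other_allele:
            raise PanelValidationError(
                f"{self.rsid}: effect and other allele are identical "
                f"({self.effect_allele})"
            )
        if not self.betas:
            raise PanelValidationError(f"{self.rsid}: empty trait set")
        unknown = set(self.betas) - set(TRAITS)
        if unknown:
            raise PanelValidationError(
                f"{self.rsid}: unknown trait label(s) {sorted(unknown)}"
            )
        if self.proxy_of is not None:
            if self.proxy_r2 is None or not self.proxy_r2 > 0.8:
                raise PanelValidationError(
                    f"{self.rsid}: proxy of {self.proxy_of} requires r2 > 0.8 "
                    f"(got {self.proxy_r2})"
                )

    @property
    def traits(self) -> frozenset[str]:
        return frozenset(self.betas)

    @property
    def is_strand_ambiguous(self) -> bool:
        return (self.effect_allele, self.other_allele) in _AMBIGUOUS_PAIRS


def combined_beta(betas: Mapping[str, float]) -> float:
    """Single-score weight for a multi-trait SNP: the signed trait beta of
    largest magnitude (ties broken by SBP < DBP < PP order)."""
    best = None
    for trait in TRAITS:
        if trait in betas:
            b = betas[trait]
            if best is None or abs(b) > abs(best):
                best = b
    assert best is not None
    return best


class ExclusionRecord(NamedTuple):
    rsid: str
    rule: str
    value: str
    stage: str


@dataclass
class Panel:
    """Ordered list of panel variants plus the append-only exclusion log."""

    variants: list[VariantSpec]
    exclusions: list[ExclusionRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [v.rsid for v in self.variants]
        dupes = sorted({r for r in ids if ids.count(r) > 1})
        if dupes:
            raise PanelValidationError(f"duplicate rsid(s): {dupes}")

    @property
    def N(self) -> int:
        return len(self.variants)

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def __iter__(self):
        return iter(self.variants)

    def __len__(self) -> int:
        return self.N

    def get(self, rsid: str) -> VariantSpec:
        for v in self.variants:
            if v.rsid == rsid:
                return v
        raise KeyError(rsid)

    def log_exclusion(self, rsid: str, rule: str, value, stage: str) -> None:
        self.exclusions.append(ExclusionRecord(rsid, rule, str(value), stage))

    def exclusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exclusions, columns=["rsid", "rule", "value", "stage"])

    def write_exclusion_log(self, path: str | Path) -> None:
        self.exclusion_frame().to_csv(path, sep="\t", index=False)


def load_panel(path: str | Path) -> Panel:
    """Read a panel TSV into a validated :class:`Panel`.

    Expected columns: ``rsid chrom pos effect_allele other_allele beta_sbp
    beta_dbp beta_pp traits [proxy_of proxy_r2]``; ``traits`` is a
    comma-joined subset of SBP,DBP,PP and each named trait must have a
    non-missing beta in its column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    missing_cols = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelValidationError(f"panel TSV missing column(s): {missing_cols}")

    dupes = sorted(df["rsid"][df["rsid"].duplicated()].unique())
    if dupes:
        raise PanelValidationError(f"duplicate rsid(s): {dupes}")

    variants: list[VariantSpec] = []
    for idx, row in df.iterrows():
        rsid = row["rsid"]
        if pd.isna(row["effect_allele"]) or pd.isna(row["other_allele"]):
            raise PanelValidationError(f"row {idx} ({rsid}): missing allele")
        trait_labels = [t.strip().upper() for t in str(row["traits"]).split(",") if t.strip()]
        unknown = [t for t in trait_labels if t not in TRAITS]
        if unknown:
            raise PanelValidationError(f"row {idx} ({rsid}): unknown trait label(s) {unknown}")
        if not trait_labels:
            raise PanelValidationError(f"row {idx} ({rsid}): empty trait set")
        betas: dict[str, float] = {}
        for trait in trait_labels:
            b = row[f"beta_{trait.lower()}"]
            if pd.isna(b):
                raise PanelValidationError(
                    f"row {idx} ({rsid}): missing beta for trait {trait}"
                )
            betas[trait] = float(b)
        proxy_of = None
        proxy_r2 = None
        if "proxy_of" in df.columns and not pd.isna(row.get("proxy_of")):
            proxy_of = str(row["proxy_of"])
            proxy_r2 = float(row["proxy_r2"])
        variants.append(
            VariantSpec(
                rsid=str(rsid),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                effect_allele=str(row["effect_allele"]).upper(),
                other_allele=str(row["other_allele"]).upper(),
                betas=betas,
                beta=combined_beta(betas),
                proxy_of=proxy_of,
                proxy_r2=proxy_r2,
            )
        )
    return Panel(variants)


def write_panel_tsv(panel: Panel, path: str | Path) -> None:
    """Write a panel back to the TSV interchange format."""
    rows = []
    for v in panel:
        rows.append(
            {
                "rsid": v.rsid,
                "chrom": v.chrom,
                "pos": v.pos,
                "effect_allele": v.effect_allele,
                "other_allele": v.other_allele,
                "beta_sbp": v.betas.get("SBP", ""),
                "beta_dbp": v.betas.get("DBP", ""),
                "beta_pp": v.betas.get("PP", ""),
                "traits": ",".join(t for t in TRAITS if t in v.betas),
                "proxy_of": v.proxy_of or "",
                "proxy_r2": v.proxy_r2 if v.proxy_r2 is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def orient_to_risk(
    panel: Panel, genotypes: "GenotypeMatrix", drop_ambiguous: bool = False
) -> tuple[Panel, "GenotypeMatrix"]:
    """Harmonize dosages to the panel and orient every coding allele to be
    the risk (blood-pressure-increasing) allele.

    Two flips may occur per variant: first the genotype dosage is aligned so
    it counts the panel's effect allele (swapping ``2 - s`` when the file
    encodes the opposite allele); then, for variants with negative beta, the
    effect/other alleles are swapped, all trait betas negated and the dosage
    flipped again, so that every output beta is strictly positive.  Applying
    the operation twice is a no-op.

    Proxy variants (``proxy_of`` set) carry the index SNP's alleles, which
    need not match the genotyped proxy; their allele pair is adopted from
    the genotype file and only the beta-sign flip is applied.

    Strand-ambiguous SNPs (A/T, C/G) are retained with a warning by default;
    set ``drop_ambiguous=True`` to exclude them (logged).
    """
    gm = genotypes.copy()
    out: list[VariantSpec] = []
    exclusions = list(panel.exclusions)
    new_panel = Panel([], exclusions)
    for v in panel:
        if v.rsid not in gm.variant_index:
            raise HarmonizationError(f"{v.rsid}: not present in genotype matrix")
        if v.is_strand_ambiguous:
            if drop_ambiguous:
                new_panel.log_exclusion(v.rsid, "strand_ambiguous",
                                        f"{v.effect_allele}/{v.other_allele}", "orientation")
                continue
            warnings.warn(
                f"{v.rsid}: strand-ambiguous alleles "
                f"{v.effect_allele}/{v.other_allele} retained",
                stacklevel=2,
            )
        ref = gm.allele_ref.get(v.rsid)
        if ref is None or v.proxy_of is not None:
            # dosage counts the effect allele by convention (dosage-TSV input),
            # or the variant is a proxy whose own alleles the panel cannot know
            if ref is not None and v.proxy_of is not None:
                v = replace(v, effect_allele=ref[0], other_allele=ref[1])
        elif tuple(ref) == (v.effect_allele, v.other_allele):
            pass
        elif tuple(ref) == (v.other_allele, v.effect_allele):
            gm.flip_variant(v.rsid)
        else:
            raise HarmonizationError(
                f"{v.rsid}: genotype alleles {ref} match neither orientation of "
                f"panel alleles ({v.effect_allele}, {v.other_allele})"
            )
        if v.beta == 0:
            raise HarmonizationError(f"{v.rsid}: beta is exactly 0, no risk direction")
        if v.beta < 0:
            flipped = {t: -b for t, b in v.betas.items()}
            v = replace(
                v,
                effect_allele=v.other_allele,
                other_allele=v.effect_allele,
                betas=flipped,
                beta=-v.beta,
            )
            gm.flip_variant(v.rsid)
        if any(b <= 0 for b in v.betas.values()):
            raise HarmonizationError(
                f"{v.rsid}: trait betas disagree in sign after orientation "
                f"({dict(v.betas)})"
            )
        gm.allele_ref[v.rsid] = (v.effect_allele, v.other_allele)
        out.append(v)
    new_panel.variants = out
    # re-run duplicate check through the constructor invariant
    return Panel(out, new_panel.exclusions), gm


def minor_allele_count(dosage_col: np.ndarray) -> float:
    """MAC from a dosage vector: ``min(sum(s), 2*n_nonmissing - sum(s))``
    over non-missing entries (imputation-aware; hard calls are the rounded
    special case)."""
    obs = dosage_col[~np.isnan(dosage_col)]
    s = float(obs.sum())
    return min(s, 2.0 * obs.size - s)


def apply_mac_filter(
    panel: Panel, genotypes: "GenotypeMatrix", threshold: int = 20
) -> Panel:
    """Drop panel variants whose minor allele count is strictly below
    ``threshold`` (default 20) in the genotyped sample."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep: list[VariantSpec] = []
    out = Panel([], list(panel.exclusions))
    for v in panel:
        if v.rsid not in genotypes.variant_index:
            raise HarmonizationError(f"{v.rsid}: not present in genotype matrix")
        mac = minor_allele_count(genotypes.column(v.rsid))
        if mac < threshold:
            out.log_exclusion(v.rsid, f"mac_lt_{threshold}", mac, "mac_filter")
        else:
            keep.append(v)
    out.variants = keep
    return Panel(keep, out.exclusions)


def resolve_proxies(
    panel: Panel,
    proxy_map: pd.DataFrame,
    genotyped_ids: Iterable[str],
    r2_threshold: float = 0.8,
) -> Panel:
    """Substitute index SNPs absent from the genotype data by their best
    proxy with LD r2 > ``r2_threshold``; drop (and log) index SNPs with no
    qualifying proxy or whose proxies are themselves not genotyped.

    ``proxy_map`` columns: ``index_rsid proxy_rsid r2``.
    """
    for col in ("index_rsid", "proxy_rsid", "r2"):
        if col not in proxy_map.columns:
            raise PanelValidationError(f"proxy map missing column '{col}'")
    r2 = proxy_map["r2"].astype(float)
    if ((r2 <= 0) | (r2 > 1)).any():
        raise PanelValidationError("proxy map r2 values must lie in (0, 1]")
    genotyped = set(genotyped_ids)
    keep: list[VariantSpec] = []
    out = Panel([], list(panel.exclusions))
    for v in panel:
        if v.rsid in genotyped:
            keep.append(v)
            continue
        cands = proxy_map[
            (proxy_map["index_rsid"] == v.rsid) & (proxy_map["r2"] > r2_threshold)
        ].sort_values(["r2", "proxy_rsid"], ascending=[False, True])
        if cands.empty:
            out.log_exclusion(v.rsid, "no_proxy", "", "proxy_resolution")
            continue
        present = cands[cands["proxy_rsid"].isin(genotyped)]
        if present.empty:
            out.log_exclusion(v.rsid, "proxy_not_genotyped",
                              ";".join(cands["proxy_rsid"]), "proxy_resolution")
            continue
        best = present.iloc[0]
        keep.append(
            replace(
                v,
                rsid=str(best["proxy_rsid"]),
                proxy_of=v.rsid,
                proxy_r2=float(best["r2"]),
            )
        )
    out.variants = keep
    return Panel(keep, out.exclusions)


def ld_prune(
    panel: Panel, genotypes: "GenotypeMatrix", r2_threshold: float = 0.8
) -> Panel:
    """Remove one variant of each pair with squared dosage correlation at or
    above ``r2_threshold``, keeping the variant with larger ``|beta|``
    (ties: the later variant in panel order is removed).  Zero-variance
    variants are excluded from the correlation computation with a warning
    and are never removed by this rule."""
    ids = panel.rsids
    if len(ids) < 2:
        return Panel(list(panel.variants), list(panel.exclusions))
    dos = pd.DataFrame(
        {v.rsid: genotypes.column(v.rsid) for v in panel}
    )
    variances = dos.var(ddof=1)
    degenerate = set(variances.index[(variances == 0) | variances.isna()])
    for rsid in sorted(degenerate):
        warnings.warn(f"{rsid}: zero dosage variance, excluded from LD pruning",
                      stacklevel=2)
    usable = [r for r in ids if r not in degenerate]
    corr2 = dos[usable].corr(min_periods=2) ** 2
    removed: set[str] = set()
    out = Panel([], list(panel.exclusions))
    beta_of = {v.rsid: abs(v.beta) for v in panel}
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            if a in removed or b in removed:
                continue
            r2 = corr2.loc[a, b]
            if np.isnan(r2) or r2 < r2_threshold:
                continue
            # drop the weaker effect; tie -> later panel order (b)
            victim = a if beta_of[a] < beta_of[b] else b
            removed.add(victim)
            out.log_exclusion(victim, f"ld_r2_ge_{r2_threshold}", round(float(r2), 6),
                              "ld_prune")
    keep = [v for v in panel if v.rsid not in removed]
    out.variants = keep
    return Panel(keep, out.exclusions)


def subset_by_trait(panel: Panel, trait: str) -> Panel:
    """Panel restricted to one blood-pressure trait (SBP, DBP or PP); each
    retained variant carries that trait's beta as its score weight."""
    trait = trait.upper()
    if trait not in TRAITS:
        raise ValueError(f"trait must be one of {TRAITS}, got {trait!r}")
    keep = [
        replace(v, betas={trait: v.betas[trait]}, beta=v.betas[trait])
        for v in panel
        if trait in v.traits
    ]
    if not keep:
        raise PanelValidationError(f"no panel variants for trait {trait}")
    return Panel(keep, list(panel.exclusions))
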