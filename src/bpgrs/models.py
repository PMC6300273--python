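"""Regression layer: quartile-based logistic and multinomial models for
hypertension, CHD and coronary-vessel burden, plus ANOVA, age-interaction
and pleiotropy screens.

All models use GRS quartile indicators with the lowest quartile as
reference.  The adjusted models add age quartiles (youngest reference),
sex, smoking, BMI category (normal-weight reference), diabetes,
hyperlipidemia, stroke and peripheral artery disease.  Analyses are
complete-case: individuals with any missing covariate are dropped (the
count is retained on the design).  Confidence intervals are Wald on the
log-odds scale, ``exp(b +/- 1.96 SE)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConvergenceError, ModelError, SeparationError
from .scores import ScoreSet, quartile_assign

logger = logging.getLogger(__name__)

#: |log-odds| beyond which a fitted term is treated as quasi-separated.
SEPARATION_BOUND = 15.0

GRS_TERMS = ["grs_q2", "grs_q3", "grs_q4"]
AGE_TERMS = ["age_q2", "age_q3", "age_q4"]
ADJUST_TERMS = AGE_TERMS + [
    "male", "smoking", "bmi_underweight", "bmi_overweight", "bmi_obese",
    "diabetes", "hyperlipidemia", "stroke", "pad",
]

#: Covariates that must be observed for an individual to enter the models.
REQUIRED_COVARIATES = [
    "age", "sex", "smoking", "bmi", "diabetes", "hyperlipidemia", "stroke", "pad",
]


def bmi_category(bmi: float) -> str:
    """WHO-style BMI classes: underweight (<18.5), normal [18.5, 25],
    overweight (25, 30], obese (>30) kg/m^2 (the printed 25-25.1 gap is
    closed at 25)."""
    if bmi < 18.5:
        return "underweight"
    if bmi <= 25.0:
        return "normal"
    if bmi <= 30.0:
        return "overweight"
    return "obese"


@dataclass
class CovariateDesign:
    """Encoded model terms plus the aligned phenotype rows they came from."""

    frame: pd.DataFrame            # dummy-coded terms, index = individual_id
    pheno: pd.DataFrame            # complete-case phenotype rows, same index
    grs_quartile: pd.Series        # raw 1-4 labels
    age_quartile: pd.Series
    n_dropped: int = 0
    score: str = "u"

    @property
    def n(self) -> int:
        return len(self.frame)

    def matrix(
        self,
        adjusted: bool,
        extra: list[str] | None = None,
        terms: list[str] | None = None,
    ) -> pd.DataFrame:
        """Design matrix with intercept.  ``terms`` overrides the default
        GRS-quartile (+ adjustment) term set entirely."""
        if terms is None:
            terms = GRS_TERMS + (ADJUST_TERMS if adjusted else [])
        x = self.frame[terms + (extra or [])].astype(float)
        return sm.add_constant(x, has_constant="add")


@dataclass(frozen=True)
class AssociationResult:
    """One fitted model term on the odds-ratio scale (or coefficient scale
    for linear models, flagged by ``model='linear'``)."""

    outcome: str
    level: int | None
    term: str
    estimate: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    model: str
    n: int

    def __post_init__(self):
        if not (self.ci_low <= self.or_ <= self.ci_high):
            raise ModelError(
                f"{self.outcome}/{self.term}: CI [{self.ci_low}, {self.ci_high}] "
                f"does not bracket estimate {self.or_}"
            )
        if not 0.0 <= self.p <= 1.0:
            raise ModelError(f"{self.outcome}/{self.term}: p={self.p} outside [0,1]")


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "level": "" if r.level is None else r.level,
                "term": r.term,
                "or": r.or_,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "model": r.model,
                "n": r.n,
            }
            for r in results
        ]
    )


def encode_covariates(
    pheno: pd.DataFrame, scores: ScoreSet, score: str = "u"
) -> CovariateDesign:
    """Build the dummy-coded design from a phenotype table and a score set.

    Rows are matched on ``individual_id``; individuals missing any required
    covariate are dropped (complete-case) with the count logged.  Age
    quartiles are computed on the analysis sample; GRS quartiles are the
    ScoreSet's labels.
    """
    ph = pheno.set_index("individual_id") if "individual_id" in pheno.columns else pheno.copy()
    sc = scores.to_frame().set_index("individual_id")
    common = [i for i in sc.index if i in ph.index]
    if not common:
        raise ModelError("no overlapping individuals between phenotypes and scores")
    ph = ph.loc[common]
    sc = sc.loc[common]

    complete = ph[REQUIRED_COVARIATES].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("complete-case filter dropped %d individuals", n_dropped)
    ph = ph[complete]
    sc = sc[complete]
    if len(ph) == 0:
        raise ModelError("no complete-case individuals")
    if (ph["bmi"] <= 0).any():
        raise ModelError("BMI must be positive")
    if (ph["age"] < 0).any():
        raise ModelError("age must be non-negative")

    grs_q = pd.Series(
        sc["quartile_u"] if score == "u" else sc["quartile_w"], index=ph.index
    ).astype(int)
    age_q = pd.Series(quartile_assign(ph["age"].to_numpy(float)), index=ph.index)
    bmi_cat = ph["bmi"].map(bmi_category)

    frame = pd.DataFrame(index=ph.index)
    for q in (2, 3, 4):
        frame[f"grs_q{q}"] = (grs_q == q).astype(int)
        frame[f"age_q{q}"] = (age_q == q).astype(int)
    frame["male"] = ph["sex"].astype(int)
    frame["smoking"] = ph["smoking"].astype(int)
    for cat in ("underweight", "overweight", "obese"):
        frame[f"bmi_{cat}"] = (bmi_cat == cat).astype(int)
    for col in ("diabetes", "hyperlipidemia", "stroke", "pad"):
        frame[col] = ph[col].astype(int)
    return CovariateDesign(
        frame=frame, pheno=ph, grs_quartile=grs_q, age_quartile=age_q,
        n_dropped=n_dropped, score=score,
    )


def _check_fit(params: pd.Series, converged: bool, outcome: str) -> None:
    if not converged:
        raise ConvergenceError(f"{outcome}: optimizer did not converge")
    big = params[params.abs() > SEPARATION_BOUND]
    if not big.empty:
        raise SeparationError(
            f"{outcome}: quasi-separation, |log-odds| > {SEPARATION_BOUND} "
            f"for term(s) {list(big.index)}"
        )


def _fit_logit(y: np.ndarray, X: pd.DataFrame, outcome: str):
    if len(np.unique(y)) < 2:
        raise ModelError(f"{outcome}: outcome has no variation")
    try:
        import warnings

        with warnings.catch_warnings():
            # separation surfaces as |log-odds| > bound below; silence the
            # fit-time warnings statsmodels emits on the way there
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.filterwarnings("ignore", message=".*[Ss]eparation.*")
            model = sm.Logit(y, X)
            res = model.fit(method="newton", maxiter=200, disp=0)
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"{outcome}: singular design ({exc})") from exc
    except Exception as exc:  # statsmodels PerfectSeparationError et al.
        if "separation" in str(exc).lower() or "Perfect" in type(exc).__name__:
            raise SeparationError(f"{outcome}: perfect separation detected") from exc
        raise
    _check_fit(res.params, bool(res.mle_retvals.get("converged", True)), outcome)
    return res


def _wald_results(
    params, bses, pvals, outcome: str, level: int | None, model_label: str, n: int
) -> list[AssociationResult]:
    out = []
    for term in params.index:
        if term == "const":
            continue
        b = float(params[term])
        se = float(bses[term])
        out.append(
            AssociationResult(
                outcome=outcome,
                level=level,
                term=term,
                estimate=b,
                se=se,
                or_=float(np.exp(b)),
                ci_low=float(np.exp(b - 1.96 * se)),
                ci_high=float(np.exp(b + 1.96 * se)),
                p=float(pvals[term]),
                model=model_label,
                n=n,
            )
        )
    return out


def fit_logistic(
    outcome: pd.Series | np.ndarray,
    design: CovariateDesign,
    adjusted: bool = True,
    outcome_label: str = "outcome",
    terms: list[str] | None = None,
) -> list[AssociationResult]:
    """Binary logistic regression of an outcome on GRS quartiles
    (+ adjustment set); returns Wald OR results per non-reference term.
    ``terms`` replaces the default predictor set (custom contrasts)."""
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ModelError(f"{outcome_label}: outcome must be binary 0/1")
    X = design.matrix(adjusted, terms=terms)
    if len(y) != len(X):
        raise ModelError(f"{outcome_label}: outcome length != design rows")
    res = _fit_logit(y, X, outcome_label)
    label = "adjusted" if adjusted else "unadjusted"
    return _wald_results(res.params, res.bse, res.pvalues,
                         outcome_label, None, label, len(y))


def fit_multinomial(
    vessels: pd.Series | np.ndarray,
    design: CovariateDesign,
    adjusted: bool = True,
    outcome_label: str = "vessels",
    terms: list[str] | None = None,
) -> list[AssociationResult]:
    """Baseline-category multinomial logit of vessel burden (0-3 diseased
    coronary vessels; baseline = 0) on GRS quartiles (+ adjustment set).

    With only two outcome levels present this is exactly binary logistic
    regression.  Each non-baseline level yields one OR + Wald CI per term.
    """
    y = np.asarray(vessels)
    levels = np.unique(y)
    if len(levels) < 2:
        raise ModelError(f"{outcome_label}: need >= 2 outcome levels")
    counts = {int(l): int((y == l).sum()) for l in levels}
    if min(counts.values()) == 0:  # pragma: no cover - unique() excludes empties
        raise ModelError(f"{outcome_label}: empty outcome level")
    X = design.matrix(adjusted, terms=terms)
    # recode to consecutive 0..J-1 with baseline = smallest level
    recode = {l: j for j, l in enumerate(sorted(levels))}
    y_enc = np.vectorize(recode.get)(y)
    try:
        model = sm.MNLogit(y_enc, X)
        res = model.fit(method="newton", maxiter=200, disp=0)
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"{outcome_label}: singular design ({exc})") from exc
    _check_fit(pd.Series(np.asarray(res.params).ravel()),
               bool(res.mle_retvals.get("converged", True)), outcome_label)
    label = "adjusted" if adjusted else "unadjusted"
    out: list[AssociationResult] = []
    params = np.asarray(res.params)        # (k_terms, J-1)
    bses = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    terms = list(X.columns)
    nonbase = sorted(levels)[1:]
    for j, lvl in enumerate(nonbase):
        p_s = pd.Series(params[:, j], index=terms)
        se_s = pd.Series(bses[:, j], index=terms)
        pv_s = pd.Series(pvals[:, j], index=terms)
        out.extend(
            _wald_results(p_s, se_s, pv_s, outcome_label, int(lvl), label, len(y))
        )
    return out


def anova_grs_by_vessels(
    scores: ScoreSet, vessels: pd.Series | np.ndarray, score: str = "u"
) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of the standardized GRS across vessel
    strata; returns ``(F, p)``."""
    y = np.asarray(vessels)
    x = scores.ugrs_std if score == "u" else scores.wgrs_std
    if len(x) != len(y):
        raise ModelError("scores and vessel vector length mismatch")
    groups = [x[y == l] for l in np.unique(y)]
    if len(groups) < 2:
        raise ModelError("ANOVA needs >= 2 strata")
    if any(len(g) < 2 for g in groups):
        raise ModelError("every vessel stratum needs >= 2 observations")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def interaction_test(
    outcome: pd.Series | np.ndarray,
    design: CovariateDesign,
    adjusted: bool = False,
    outcome_label: str = "outcome",
) -> tuple[float, int, float]:
    """Likelihood-ratio test of GRS-quartile x age-quartile interaction:
    the model with all 9 product terms against the model without, chi-square
    with 9 degrees of freedom.  Returns ``(LR statistic, df, p)``."""
    y = np.asarray(outcome, dtype=float)
    products = {}
    for gq in (2, 3, 4):
        for aq in (2, 3, 4):
            col = design.frame[f"grs_q{gq}"] * design.frame[f"age_q{aq}"]
            products[f"grs_q{gq}:age_q{aq}"] = col
    prod = pd.DataFrame(products, index=design.frame.index)
    if (prod.sum(axis=0) == 0).any():
        dead = list(prod.columns[prod.sum(axis=0) == 0])
        raise ModelError(f"interaction inestimable, empty cell(s): {dead}")
    base_terms = GRS_TERMS + AGE_TERMS + (
        [t for t in ADJUST_TERMS if t not in AGE_TERMS] if adjusted else []
    )
    X0 = sm.add_constant(design.frame[base_terms].astype(float), has_constant="add")
    X1 = pd.concat([X0, prod.astype(float)], axis=1)
    res0 = _fit_logit(y, X0, f"{outcome_label} (reduced)")
    res1 = _fit_logit(y, X1, f"{outcome_label} (interaction)")
    lr = 2.0 * (res1.llf - res0.llf)
    df = 9
    return float(lr), df, float(stats.chi2.sf(lr, df))


def pleiotropy_screen(
    scores: ScoreSet,
    risk_factors: pd.DataFrame,
    score: str = "u",
) -> list[AssociationResult]:
    """Test the GRS for association with non-blood-pressure risk factors.

    Binary factors (diabetes, smoking, hyperlipidemia) are regressed on GRS
    quartiles by logistic model; continuous BMI by ordinary least squares
    (those rows are flagged ``model='linear'`` and carry the coefficient,
    not an OR).  Returns one result per quartile term per factor; an empty
    factor frame yields an empty list.
    """
    out: list[AssociationResult] = []
    if risk_factors.shape[1] == 0:
        return out
    qser = pd.Series(scores.quartiles(score), index=scores.individual_ids)
    if len(risk_factors) == len(qser) and not risk_factors.index.isin(qser.index).all():
        q = qser.to_numpy()  # positional alignment (anonymous index)
    else:
        q = qser.reindex(risk_factors.index)
        if q.isna().any():
            raise ModelError("risk-factor rows not covered by the score set")
        q = q.to_numpy()
    dummies = pd.DataFrame(
        {f"grs_q{k}": (q == k).astype(int) for k in (2, 3, 4)},
        index=risk_factors.index,
    )
    X = sm.add_constant(dummies.astype(float), has_constant="add")
    for factor in risk_factors.columns:
        y = np.asarray(risk_factors[factor], dtype=float)
        is_binary = np.isin(y[~np.isnan(y)], (0.0, 1.0)).all()
        if is_binary:
            res = _fit_logit(y, X, f"pleiotropy:{factor}")
            out.extend(
                _wald_results(res.params, res.bse, res.pvalues,
                              factor, None, "pleiotropy-logistic", len(y))
            )
        else:
            ols = sm.OLS(y, X).fit()
            for term in GRS_TERMS:
                b = float(ols.params[term])
                se = float(ols.bse[term])
                out.append(
                    AssociationResult(
                        outcome=factor, level=None, term=term,
                        estimate=b, se=se, or_=b,
                        ci_low=b - 1.96 * se, ci_high=b + 1.96 * se,
                        p=float(ols.pvalues[term]), model="linear", n=len(y),
                    )
                )
    return out


def run_sensitivity(
    gm,
    panel,
    pheno: pd.DataFrame,
    subset: str,
    score: str = "u",
    adjusted: bool = True,
    missing: str = "mean",
) -> dict:
    """Re-run the CHD and vessel-burden models on a phenotype subset.

    ``subset='no_hypertension'`` keeps individuals without diagnosed
    hypertension; ``'no_prior_ami'`` excludes previous myocardial
    infarction.  GRS quartiles are re-computed on the subset before
    refitting, so quartile boundaries reflect the analysis sample.
    """
    from .scores import compute_scores

    if subset == "no_hypertension":
        keep = pheno["hypertension"] == 0
    elif subset == "no_prior_ami":
        keep = pheno["prior_ami"] == 0
    else:
        raise ValueError(f"unknown subset {subset!r}")
    sub = pheno[keep].copy()
    if len(sub) < 8:
        raise ModelError(f"subset {subset}: too few individuals for quartiles")
    ids = list(sub["individual_id"]) if "individual_id" in sub.columns else list(sub.index)
    gm_sub = gm.subset_individuals([s for s in gm.individual_ids if s in set(ids)])
    scoreset = compute_scores(gm_sub, panel, missing=missing)
    design = encode_covariates(sub, scoreset, score=score)
    chd = design.pheno["chd"]
    vessels = design.pheno["vessels"]
    results = {
        "subset": subset,
        "n": design.n,
        "chd": fit_logistic(chd, design, adjusted=adjusted,
                            outcome_label=f"chd[{subset}]"),
        "vessels": fit_multinomial(vessels, design, adjusted=adjusted,
                                   outcome_label=f"vessels[{subset}]"),
    }
    return results
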