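# Methods

This note documents the statistical procedures implemented in `bpgrs`,
the choices made where conventions differ, and what the synthetic cohort
generator does and does not emulate.

## Panel handling and allele harmonization

A panel variant carries one effect size per blood-pressure trait (SBP,
DBP, PP) it reached genome-wide significance for.  Where a single score
weight is needed for a multi-trait SNP, the combined beta is the trait
beta of largest magnitude (ties broken in SBP < DBP < PP order); the
per-trait scores (`subset_by_trait`) always use the trait's own beta.

Harmonization proceeds in two steps per variant.  First the genotype
dosage is aligned to the panel's allele pair: if the genotype file counts
the panel's *other* allele, the dosage is recoded `s → 2 − s`.  Second,
risk orientation: variants with negative beta have effect/other alleles
swapped, all trait betas negated and the dosage flipped again, so every
oriented beta is strictly positive.  The operation is idempotent, and a
beta of exactly zero is rejected (no risk direction exists; a zero-weight
SNP would contribute nothing to the weighted score yet inflate the
unweighted one).  Variants whose alleles match neither orientation raise
an error naming the rsid.  Strand-ambiguous SNPs (A/T, C/G) are retained
with a warning by default — panel and genotypes are assumed harmonized to
one genome build — and can be dropped with `drop_ambiguous`.

Proxy substitution replaces an ungenotyped index SNP by its best proxy
with LD r² > 0.8, carrying the index SNP's weight and trait membership.
Because the panel table does not describe the proxy's own alleles, a
substituted variant adopts the genotype file's allele pair at orientation
time and only the beta-sign flip is applied.  Index SNPs without a
qualifying proxy are dropped and logged (`no_proxy`), as are those whose
proxies are not genotyped (`proxy_not_genotyped`); every exclusion at any
stage lands exactly once in the append-only exclusion log with its rule
and value.

Minor allele count uses dosage sums, `min(Σs, 2·n_obs − Σs)`, so imputed
soft calls contribute fractionally; hard calls are the rounded special
case.  The MAC filter is strict (`MAC < 20` removed).  LD pruning computes
squared pairwise dosage correlation across individuals; of each pair at or
above the threshold the variant with smaller |beta| is removed, with ties
going against the later variant in panel order — any rule here reproduces
a panel with no correlated pairs, but this one is deterministic and keeps
the stronger signal.  Zero-variance variants are excluded from the
correlation with a warning and are never removed by this rule.

## Genotype QC

QC runs in the order variant missingness → sample call rate →
Hardy–Weinberg, with strict inequalities exactly as stated by the
thresholds (a variant at exactly 5% missingness, or a sample at exactly
95% call rate, is retained).  HWE is computed on hard calls: stored
integer genotypes when available, otherwise dosages rounded only when
within ±0.1 of an integer (anything softer is treated as missing, since
HWE on continuous dosages is ill-defined).  The default test is the 1-df
chi-square goodness of fit against p², 2pq, q² at the observed allele
frequency, without continuity correction; an exact conditional test
(enumeration of heterozygote counts at fixed allele counts, optional
mid-p) is available as `method="exact"`.  The chi-square approximation
agrees with the exact test within 0.1 absolute on genotype counts up to
n = 200 (verified in the test suite against an independent
rational-arithmetic enumeration); near the filter threshold of 1e-4 with
common alleles the two agree far more closely.  Monomorphic variants have
no HWE departure to test and are assigned p = 1 with a warning.  HWE is
applied to all hard-callable variants, proxies included.

Dosage-TSV input carries no allele columns; its variants are stored with
`allele_ref = None`, meaning "the dosage already counts the panel's
effect allele".  This is the one place the container relaxes the rule
that every variant knows its counted allele, and it only affects inputs
that by construction cannot state one.

## Scores, standardization, quartiles

Missing dosages at scoring time are mean-imputed per variant (twice the
observed allele frequency) by default; `drop` (exclude the individual)
and `zero` are selectable.  Standardization uses the sample SD (n − 1);
quartile-based analyses are invariant to that choice.  Quartile cuts are
nearest-rank empirical 25/50/75 percentiles; tied values share the
quartile of their common value, assigned to the lower interval.  This
makes assignments invariant under monotone transformations (in particular
raw vs standardized scores give identical labels) and produces the
near-equal-but-unequal group sizes characteristic of integer-valued
scores.

## Association models

All models code the GRS quartile with the lowest quartile as reference.
The adjusted models add age quartiles (youngest reference, computed on the
analysis sample), sex, smoking, BMI category, diabetes, hyperlipidemia,
stroke and PAD.  BMI categories are underweight < 18.5, normal
[18.5, 25], overweight (25, 30], obese > 30 kg/m² — the conventional
printed 25–25.1 gap is closed at 25.  Analyses are complete-case; the
dropped count is kept on the design.  No multiple-testing correction is
applied; the run manifest records the number of tests performed.

Binary outcomes use maximum-likelihood logistic regression (Newton, 200
iterations); vessel burden uses baseline-category multinomial logit,
which reduces exactly to the binary model when only two levels are
present (asserted to 1e-6 in tests).  Confidence intervals are Wald on
the log-odds scale, `exp(b ± 1.96·SE)`.  Any fitted |log-odds| above 15
is treated as quasi-separation and raised as an error rather than
reported as an unstable OR.  The ANOVA across vessel strata is one-way
fixed-effects on the standardized score; the GRS × age interaction check
is a likelihood-ratio test of all nine product terms (chi-square, 9 df).
The pleiotropy screen regresses each binary risk factor (diabetes,
smoking, hyperlipidemia) on the GRS quartiles by logistic model and BMI
by ordinary least squares; linear rows are flagged `model="linear"` and
carry coefficients, not odds ratios.

Sensitivity analyses (`no_hypertension`, `no_prior_ami`) re-compute the
score quartiles on the subset before refitting, so quartile boundaries
always reflect the analysis sample.  The "unadjusted" models contain the
GRS quartile terms only.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:
independent biallelic SNPs with effect-allele frequencies uniform on
[0.05, 0.95], dosages Binomial(2, p) per individual (HWE by
construction), positive exponential effect sizes (mean 0.5 mmHg per
allele), and ~24% multi-trait SNPs.  Defaults are the angiography-cohort
conditions the pipeline targets: 4,809 individuals, 266 SNPs, covariate
marginals of 64.2% male, 24.0% smoking, 17.5% diabetes, 57.8%
hyperlipidemia, 7.9% stroke, 6.3% PAD, age ≈ N(65.5, 11.9²) and BMI ≈
N(27.5, 4.6²) (both truncated to plausible clinical ranges).

Hypertension is Bernoulli with logit-linear dependence on the
standardized unweighted GRS (default 0.25 log-odds per SD around a
56.3% baseline).  Vessel burden is drawn from a baseline-category
multinomial — the same family the analysis fits, so recovery tests are
well-specified — with intercepts defaulting to the closed-form values for
a 46.1/26.6/13.9/13.4% marginal distribution and per-quartile log odds
ratios defaulting to a dose-response operating point: none on 1-vessel
disease, (–, 1.33, 1.36) on 2-vessel and (1.32, 1.77, 1.65) on 3-vessel
disease for quartiles 2–4.  Significant CHD is defined as ≥ 1 diseased
vessel; prior AMI is Bernoulli with log-odds linear in the vessel count.
Every generating effect is recorded in a `GroundTruth` object.

`calibrate_intercepts` solves intercepts against target marginals on a
large fixed sample of linear predictors (200,000 by default): bisection
for the binary model, iterated proportional adjustment of the softmax
means for the multinomial, both deterministic given the seed.  With all
effects zero it reduces to the closed forms `logit(p)` and `log(p_k/p_0)`.
The calibration sample draws the standardized GRS from N(0, 1), the
asymptotic distribution of a standardized sum of a couple of hundred
independent binomials; achieved marginals are within 0.5 percentage
points of target at n = 100,000.

What the generator does **not** emulate: LD between panel SNPs (the real
panel is LD-pruned, so variants are simulated independent), population
stratification, covariate–covariate correlation (marginals are
independent unless effects are configured), genotyping batch effects, and
ascertainment into an angiography cohort.  Passing tests therefore
demonstrate correctness of the pipeline's algebra and the calibration and
recovery behaviour of its estimators under the assumed model — not
robustness to confounding or model misspecification in real cohorts.  An
individual cohort's odds-ratio point estimates depend on its allele
frequencies and case mix and are not reproduction targets.

## Problem sizes and numerical choices

The stochastic test suites run at sizes chosen to make Monte-Carlo error
small relative to the bands they assert: type-I error of the quartile
Wald tests pooled over the three null contrasts of 500 replicates at
n = 4,000 (band 0.05 ± 0.015, ≈ 2σ); ANOVA null p-values over 1,000
replicates against uniformity (KS at α = 0.01); interaction-LRT size over
400 replicates at n = 2,000 (3σ binomial band); CI coverage over 200
replicates at n = 5,000 (0.95 ± 0.02); single-fit parameter recovery at
n = 50,000 (within 3 Wald SEs of truth); error-shrinkage across
n ∈ {2,000, 8,000, 32,000}.  Optimizer: Newton with a 200-iteration cap;
non-convergence and quasi-separation (|log-odds| > 15) are errors, never
silently reported.  All randomness flows through explicit integer seeds;
identical seed and configuration reproduce every output byte-for-byte.

## Known limitations

* Multinomial and logistic fits require every configured outcome level to
  be populated; very small subsets fail fast rather than returning
  unstable estimates.
* The exact HWE test enumerates heterozygote counts and is intended for
  per-variant counts, not genome-scale scans (the chi-square default is
  vectorized-friendly and is what the filter uses).
* Proxy variants trust the genotype file's allele orientation (see
  above); a proxy genotyped on the wrong strand cannot be detected from
  the panel table alone.
* The pipeline models prevalent outcomes only; no incidence or survival
  modelling is included.
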