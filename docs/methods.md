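# Methods

This note records the statistical procedures `ewascan` implements, the
assumptions behind them, the parameters that matter, and the design choices
made where more than one convention was defensible.

## Scope and data model

The package screens harmonized environmental factors against a binary
phenotype in one or more complex-survey cohorts. A cohort is a participant
table carrying: a continuous phenotype measure (by default fasting blood
glucose in mg/dL, dichotomized at 126), demographic covariates (age in
years, sex, BMI in kg/m², ethnicity, poverty-income ratio), survey design
columns (stratum, PSU, sampling weight), exposure columns keyed by
harmonized symbol, and optional sensitivity columns (self-reported
diagnosis flag, triglycerides, cholesterol in mg/dL, dietary-recall
amounts, supplement-use count). The codebook supplies per-factor metadata:
cohort-specific aliases, environmental class, scale
(continuous/categorical), units, detection limit, categorical referent
level, and a subset-targeted flag. Harmonization is strictly
codebook-driven; there is no fuzzy matching of variable names.

### Case definition and factor filters

Cases are participants with phenotype ≥ threshold (inclusive); rows with a
missing phenotype are excluded, never imputed. A factor is dropped when
strictly more than 90% of its *non-missing* observations fall below the
assay detection limit (missing is not evidence of being below LOD), or when
the assay targeted a population subset. Below-LOD values of retained
continuous factors are substituted with LOD/√2 before log transformation —
the standard convention for national-survey laboratory data; LOD/2 and
no-substitution are available as options. Missingness is handled
complete-case per fitted model (phenotype, covariates, and the one exposure
under test), so per-factor sample sizes vary.

## Survey-weighted logistic regression

Point estimation maximizes the weighted Bernoulli pseudo-likelihood by
Newton/IRLS starting at β = 0, with step-halving whenever a step decreases
the pseudo-likelihood; convergence is max|Δβ| < 1e-8 within 100 iterations.
Rank deficiency is detected up front (QR, naming the collinear terms);
separation is reported when coefficients diverge or fitted probabilities
pin at 0/1 without convergence; a non-converged fit without separation is
returned flagged and its p-values treated as missing downstream.

The covariance is the Taylor-linearization sandwich A⁻¹BA⁻¹: A is the
weighted information X'·diag(w μ(1−μ))·X at the estimate; B sums, per
stratum h with n_h PSUs, n_h/(n_h−1) times the outer products of PSU-level
score totals centered at their stratum mean. The with-replacement
approximation is used throughout (no finite-population correction),
matching common national-survey practice. Wald tests refer β/SE to a t
distribution with #PSU − #strata degrees of freedom; a standard-normal
reference is available as an option (`reference="normal"`), and on
synthetic studies at the default scale the two give rejection rates within
Monte-Carlo error of each other at α = 0.02, the t being slightly
conservative.

A stratum containing a single PSU has no defined variance contribution.
The default policy is a hard error; an opt-in `lonely_psu="certainty"`
treats such strata as sampled with certainty (zero contribution). Silent
variance deflation was judged worse than a loud failure.

### Exposure transformation

Continuous exposures enter as z = (log₁₀x − m)/s with m, s the mean and
sample SD (denominator n−1) computed *unweighted* on that model's
complete-case set, so exp(β) is the odds ratio per one SD of log exposure.
The stats are recorded on every result for audit and for mapping z back to
raw levels (10^(m ± s)). Whether to weight these summary statistics is a
convention choice; unweighted-per-analysis-set is the simplest reproducible
one and is applied consistently, including recomputation on the pooled set
for combined fits. Categorical factors enter as dummies against the
codebook's referent level (the "negative" assay result), never against the
most frequent level. Age and BMI enter linearly and untransformed;
ethnicity referent is "white" and SES referent the 3rd (highest) tertile,
with tertiles cut unweighted within cohort on the poverty index.

## Permutation FDR and multi-cohort validation

The null distribution shuffles case/control labels uniformly across each
cohort's classified rows and recomputes every factor's regression; one
shared permutation per cohort per replicate (not per factor) preserves the
cross-factor correlation of null statistics, which the validation-stage
counting needs. B defaults to 1000; a reduced-B mode (the tests use 100)
widens the Monte-Carlo error of the FDR ratio by √10 but changes nothing
structurally. Failed permutation fits are dropped from the null pool and
counted; more than 1% failures triggers a warning.

FDR(α) = (fraction of pooled null p ≤ α) / (fraction of observed p ≤ α),
missing when there are no observed discoveries. Significance calls are
inclusive (p ≤ α). Validation requires significance at α (default 0.02) in
at least two cohorts; factors measured in fewer than two cohorts are
*ineligible*, which is reported distinctly from failing. The validation FDR
pairs replicate b across cohorts, counts factors significant in ≥2 permuted
cohorts, and divides the mean count by the number of observed validations.

## Combined-cohort estimation and prototype risks

Pooling k cohorts divides each original weight by k (the "average of the
original weights" rule: each participant appears once, so averaging over
cycles is a 1/k rescaling — survey-program special cases for particular
cycle pairs are deliberately not implemented), namespaces stratum/PSU
labels by cohort, and adds a cohort indicator whose referent is the most
recent member cohort. That referent is also the reference cohort for
predictions. Cohorts not measuring a factor are dropped from that factor's
pool and logged.

Predicted risks are reported for a fixed prototype profile — age 45, male,
white, BMI 27, middle SES tertile, referent cohort — at exposure z = −1
("low") and z = +1 ("high"), with the raw levels 10^(m ± s) alongside. The
identity logit(p_high) − logit(p_low) = 2β holds to machine precision by
construction, which also means a printed per-SD OR and low-exposure risk
determine the high-exposure risk via
p_high = expit(logit(p_low) + 2 ln OR) (`risk_shift`). Probabilities quoted
in prose are rounded to the nearest percent.

### Sensitivity analyses

Three composable refits of a validated factor's combined model probe the
robustness of an association:

- **exclude_diagnosed** — reverse-causality probe: drop participants
  self-reporting a physician diagnosis and refit on biochemically defined
  cases only;
- **lipid_adjust** — add log₁₀ triglycerides and log₁₀ total cholesterol
  (lipophilic exposures concentrate in fat, which is itself associated with
  the phenotype);
- **diet_adjust** — add log₁₀ dietary-recall amounts for a configurable
  food-component list plus an integer supplement-use count;
- **combined_adjust** — lipid and diet adjustments simultaneously.

Each result reports the adjusted OR/CI/p next to baseline and the relative
change 100·(OR_adj/OR_base − 1). Nonpositive values under a log₁₀ term are
a hard error with the offending rows listed; any offset policy must be
applied explicitly by the caller.

## The synthetic-study generator

`ewascan.simulate` draws multi-cohort studies with the structural features
the pipeline assumes: right-skewed exposures (lognormal on the log₁₀ scale,
location 1.0, scale 0.5 by default), equicorrelated blocks of factors
within a class (ρ = 0.3, block size 4), LOD censoring at a configurable
quantile (default 15% below LOD, with the machine value retained so the
filter and substitution paths are exercised), lognormal design weights
(CV ≈ 0.53, independent of outcome by default, with an informative-weights
switch), stratified cluster labels (15 strata × 3 PSUs), and a logistic
outcome model on population-standardized log exposures plus covariate
effects (age +0.03/yr, BMI +0.07/unit, female −0.3, SES tertile +0.3/+0.1)
matching the adjustment set the scan fits. The intercept is calibrated per
cohort (root-finding on the realized linear predictor) so the achieved
prevalence equals the target (default 6.5%) rather than overshooting by
Jensen's inequality. The phenotype is a deterministic transform of the
latent case label (cases ≥ 130, controls < 120 mg/dL, noise bounded away
from the 126 threshold) so classification exactly inverts the generative
status and upstream tests stay sharp.

Two generator design points deserve emphasis. First, factors carrying a
planted effect occupy singleton correlation blocks: a null factor
correlated with a causal one has a genuine nonzero marginal association
(the exposure analogue of linkage disequilibrium), which would make the
truth table's zeros ambiguous. Second, the parameter-recovery preset
(`recovery_config`) uses no LOD censoring and generates outcomes from
exactly the covariate terms the scan adjusts for, so the planted per-SD
log-OR is the true coefficient of the fitted model; with censoring or
omitted-term mismatch the estimand would differ from the planted value by
design, conflating generator and estimator.

What the generator does *not* emulate: realistic marginal distributions per
analyte, within-PSU outcome correlation (cluster labels are assigned at
random), item nonresponse patterns that depend on exposure level, or
measurement error. Passing tests therefore demonstrate the statistical
machinery under the stated structure, not performance on any particular
real survey.

The canonical demo preset (`canonical_study_config`) is 4 cohorts of 2500
participants, 200 factors in 21 classes with 75% of factors measured in
every cohort and the rest in one, 5 planted factors spanning per-SD ORs
1.5–2.2 and 0.6, 15% LOD censoring, and 5% exposure missingness.

## Problem sizes used by the test suite

The stochastic test suites run at a reduced permutation budget chosen as
the package's own test scale: FDR-calibration checks use a fully null
4-cohort study of 2500 participants and 150 factors with B = 100 label
shuffles; false-validation behavior additionally averages over 12
independent null studies; effect recovery uses 400 single-factor replicates
at n = 2500; the end-to-end check runs 10 replicates of the canonical
preset. Tolerances are Monte-Carlo standard errors computed inside each
test, binomial where counts are binomial.

## Known limitations

- ML logistic estimates carry the classic finite-sample bias away from
  zero; at roughly 160 cases and 10 model terms this is about +2% on a
  per-SD log-OR, and it is visible in the recovery suite once Monte-Carlo
  error drops below it. The package implements the plain pseudo-ML
  estimator deliberately (it is the standard design-based method); no
  Firth-type correction is applied.
- No replicate-weight (BRR/jackknife) variance, no Poisson/linear survey
  GLMs, no multiple imputation, no interaction or exposure-mixture models:
  single exposure at a time by design.
- Externally pre-lipid-adjusted exposure variables are not used; lipid
  adjustment is always by explicit covariates.
- The validation rule treats cohorts symmetrically and requires the same
  working α everywhere.
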