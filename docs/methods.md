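# Methods

This note documents the statistical models implemented in `expomix`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Exposure standardization

Raw spot-urine biomarker concentrations are processed in a fixed order:
below-LOD handling on the raw assay scale first (the LOD is a property
of the assay, not of any corrected scale), then dilution correction,
then log-scale time-of-day and batch adjustment. Each stage is
independently skippable because cohorts differ in which corrections
their protocol requires (`CohortAssayProfile`).

* **Dilution.** Levine–Fahey for specific gravity,
  `E_sg = E0 (Sg_med − 1)/(Sg0 − 1)`, and Boeniger for creatinine,
  `E_cr = E0 · Cr_med/Cr0`. The reference medians are computed over the
  study sample being standardized. Specific gravity at or below 1 and
  non-positive creatinine are hard errors naming the sample.
* **LOD handling.** Phthalates (detection typically well above 50%)
  use LOD/√2 substitution. Bisphenols, whose detection rates are lower,
  use multiple imputation: a lognormal is fitted by maximum likelihood
  with censored observations entering through Φ((log LOD − µ)/σ), and
  each censored value is drawn from the fitted distribution truncated
  to (0, LOD), independently per imputation (default m = 5 datasets).
  Detected values are never altered. An all-censored analyte is a hard
  error recommending exclusion rather than a silent guess.
* **Time of day.** The residual method with a linear + quadratic
  polynomial in clock hour; quadratic captures diurnal curvature
  cheaply, and the degree is configurable. Adjusted values are the
  regression residuals plus the grand mean, so they are uncorrelated
  with the time terms, the mean is preserved and the variance cannot
  increase.
* **Batch.** Per-batch mean-centering on the log scale (batch means
  equalized to the grand mean). Published batch-weighting schemes are
  generally not reproducible from their citations; mean equalization is
  the minimal adjustment with a provable invariant (zero between-batch
  variance of means) and is labelled as such. Batches with fewer than
  two samples are left unadjusted with a warning.
* **Missing dilution measurements** are imputed by linear regression on
  sampling and anthropometric covariates (at least 30 complete rows
  required); specific-gravity predictions are floored at 1.001 so the
  Levine–Fahey denominator stays positive.

## Estimated daily intake

`EDI = C_adj · UV · MW_parent / (FUE · W · MW_metabolite)` in
µg/kg body weight/day. The constants table (molecular weights from
molecular formulas; molar FUE defaults from the biomonitoring
literature) ships versioned with the package and is user-overridable;
the DEHP intake uses the molar sum of the available oxidative
metabolites with the combined FUE of exactly that subset, so restricted
metabolite sets (cohorts that lack MEHP or MECPP) rescale the intake by
a subject-constant factor and leave log2-scale effect estimates
unchanged. DBP is the arithmetic sum of the DiBP and DnBP intakes.
MCPP, a non-specific metabolite of several high-molecular-weight
phthalates, is analysed as a urinary concentration.

Pregnancy urine volume defaults to 1.6 L/day. Weight at sampling
follows the IOM gestational weight-gain guideline encoded as: linear
gain to 1.25 kg by week 13 (midpoint of the 0.5–2 kg first-trimester
range), then a BMI-category weekly rate chosen so the cumulative gain
at week 40 equals the category's total-gain midpoint (e.g. 13.75 kg
for normal BMI). Child UV/W is a piecewise-constant age table
(0.047 L/day/kg under age 1 declining to 0.030 at ages 4–6), from
normative urine-output values.

Prenatal repeated samples are averaged on the natural scale and then
log2-transformed — the estimand is the effect of doubling the average
exposure; averaging log values would target a different quantity.
Trimester boundaries default to the obstetric convention (T1 < 14
weeks, T2 14–27, T3 ≥ 28) and are configurable, since no universal
definition exists.

## Outcome alignment

Postnatal lagged windows are half-open: the exposure at time t is
paired with outcome assessments at ages in (t, t′], where t′ is the
subject's next exposure time (the last window extends to age five).
Multiple assessments in a window aggregate as any-positive — the
questionnaire items are "ever had X" phrasings — and the row's age
covariate is the mean of the aggregated assessment ages. An assessment
at exactly the exposure time is excluded (strictly future outcomes
only), so every analysis row satisfies temporal precedence by
construction.

## Single-compound models

Log-link Poisson GEE with exchangeable working correlation clustered
by child; robust sandwich covariance (valid even when the working
correlation is wrong); Wald 95% CIs on the log scale with z = 1.96.
With the exposure on the log2 scale, exp(β) is the risk ratio per
doubling. Convergence follows the statsmodels GEE defaults with a
relative-change tolerance of 1e-8; coefficients exceeding 50 in
absolute value raise a distinct complete-separation error, since small
trimester strata can separate. No multiple-testing correction is
applied: the analysis is a pattern-screening design that prioritizes
signal detection over familywise error control.

Restricted cubic splines use the Harrell basis (linear beyond the
boundary knots), 3 knots at the 10th/50th/90th exposure percentiles;
non-linearity is a robust Wald test on the non-linear coefficients.
Dose–response curves are predicted with continuous covariates at their
means and categorical covariates at their reference (first) level,
expressed relative to the median exposure. Sex effect-measure
modification adds an exposure-by-sex interaction; stratum estimates
are the interaction-model contrasts, and the interaction p-value is
the robust Wald test of the product term.

## Mixture models (quantile g-computation)

Each compound's exposure is replaced by its empirical quantile score
0..q−1, computed from average ranks through ⌊rank·q/(n+1)⌋ — a
deterministic tie rule that keeps tied values in one bin and makes the
scores invariant to monotone transforms. The underlying log-link
Poisson risk model includes all scores plus covariates; ψ = Σβⱼ is the
log RR of a joint one-quantile increase, and βⱼ/Σ(same-sign β) gives
the signed weights.

The underlying model is fitted as a Poisson GLM (independence working
correlation); repeated measures are honoured by the subject-level
bootstrap, which resamples children with replacement, re-quantizes and
refits inside each replicate, and takes percentile CIs (default 1000
replicates; non-convergent replicates are dropped, more than 10%
dropped is an error). The marginal target matches the GEE
single-compound analysis; an exchangeable-GEE refit of the underlying
model is available through the same design matrix if a conditional
sensitivity check is wanted. The inner solver is a small IRLS
implementation verified against statsmodels to 1e-13, which keeps
full bootstrap runs fast.

Non-linear mixture curves raise q to 20 and add per-compound quadratic,
cubic or restricted-cubic-spline terms; the specification with the best
AIC (from the underlying Poisson likelihood) is selected, and the curve
is the g-computation prediction — mean predicted risk with every
compound set to joint quantile s, covariates at their observed values —
relative to s = 0. Spline knots are frozen on the observed scores so
counterfactual predictions use the same basis as the fit. Sex
interaction enters by interacting every score with sex, giving per-sex
ψ and a bootstrap p-value for the ψ difference.

Default mixture membership: prenatal analyses include DEP, DBP, BBzP,
DEHP, MCPP and BPA; postnatal analyses drop BPA and add nothing —
compounds without adequate measurement coverage are excluded rather
than imputed, and children missing any mixture compound are excluded.

## Sensitivity suite

* **E-values:** E = RR + √(RR(RR−1)) for RR ≥ 1, applied to 1/RR for
  protective estimates; the CI-bound E-value uses the limit nearer the
  null and is 1 when the interval crosses 1.
* **Meta-analysis:** τ² by restricted maximum likelihood (bounded
  scalar optimization of the REML likelihood), pooled estimate by
  inverse-variance weights 1/(SEᵢ² + τ²), I² = max(0, (Q − df)/Q)·100
  from Cochran's Q. Pooling is on the log-RR scale.
* **Stabilized IPW:** logistic selection model on the inception
  sample; weight = P(inclusion)/P(inclusion | covariates), truncated at
  the 1st/99th percentiles by default (switchable) for variance
  control. Near-perfect predictors of inclusion raise an error.
* **MICE:** chained equations (linear models with Gaussian noise for
  continuous covariates, sequential logistic draws for categorical),
  default 5 datasets × 20 iterations, Rubin's rules pooling on the
  log-RR scale.

## Synthetic-cohort generator

The generator reproduces the statistical structure the analysis
assumes, with defaults calibrated to the pooled study's published
marginals (`expomix.presets`): lognormal exposures at the published
GM/GSD per compound and period, overall outcome prevalences, covariate
frequencies, and the published sample sizes.

* **Exposures** are multivariate lognormal; the log-scale variance
  splits into a subject-level share (`exposure_icc`, default 0.5,
  correlated across compounds by a user-supplied matrix — exposure
  correlations are not published numerically, so the matrix is an
  input, not an assertion) and independent within-subject noise.
* **Outcomes** follow the marginal log-link risk model
  `risk = baseline · exp(Σ β · (log2 x − log2 GM))`, truncated at 0.99
  with a logged warning. Within-subject dependence across repeated
  assessments comes from a Gaussian copula (a subject-shared normal
  component on the latent uniform, correlation `outcome_dependence`,
  default 0.3). A multiplicative frailty was considered and rejected:
  at a 60% baseline prevalence a mean-one lognormal frailty pushes a
  material share of risks past 1, and the truncation attenuates the
  marginal slope the estimators target; the copula preserves the
  marginal model exactly at any prevalence.
* **Mixture truths** apply ψ/J to each compound's centred quantile
  score computed from the per-assessment exposure matrix, so the
  injected joint one-quantile effect is exactly the quantity the
  quantile g-computation estimator targets.
* **Design alignment:** postnatal presets place one outcome assessment
  inside each lagged exposure window (ages 1.5/2.5/3.5 for sampling at
  1/2/3 years). With several assessments per window, any-positive
  aggregation changes the estimand away from the injected
  per-assessment risk ratio; one assessment per window makes the
  published RR a well-defined simulation truth.
* **Covariates** are drawn independently from stated marginals, with
  missing-completely-at-random masking; optional switches let one
  covariate shift both exposure and outcome (to exercise confounder
  adjustment and IPW).

What the generator does **not** emulate: cohort recruitment and
attrition, assay chemistry, between-cohort protocol heterogeneity
beyond per-cohort parameter sets, real exposure correlation structure,
and missing-not-at-random mechanisms. Passing recovery tests therefore
demonstrates estimator correctness under the assumed data-generating
model, not robustness to violations of it.

## Problem sizes

Recovery checks use the published scale: prenatal n = 2900 with two
pregnancy samples and two outcome assessments, postnatal n = 1700 with
three lagged windows, mixture n = 1650 with five compounds. Tests and
the acceptance script run 50 replicates per check with bootstrap
n = 200 where bootstraps are nested; the bootstrap default for a
single analysis is 1000 replicates.

## Known limitations

GEE estimates are marginal; the conditional (random-intercept) variant
of the mixture model is exposed only through the bootstrap's agnostic
CI, not as a separate likelihood fit. The MICE implementation uses
sequential binary logits for multi-level categoricals rather than a
full multinomial draw. The E-value CI bound assumes a Wald-type
symmetric interval on the log scale. Batch adjustment is mean
equalization, not a variance-component model.
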