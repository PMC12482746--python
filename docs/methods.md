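# Methods

This note records the modelling choices behind `cakival`: what the synthetic
cohort generator does and does not emulate, how the estimators are defined,
and the numerical conventions used throughout.

## Outcome definitions

C-AKI and severe C-AKI are derived from the serum-creatinine trajectory
within 14 days of cisplatin exposure: C-AKI is an absolute rise ≥ 0.3 mg/dL
from baseline **or** a ≥ 1.5-fold rise; severe C-AKI is a ≥ 2.0-fold rise
**or** initiation of renal replacement therapy (RRT).  All comparisons are
inclusive (a ratio of exactly 2.0 is severe), day 0 is the pre-dose
baseline, and points beyond the window never affect labels.  Note the
0.3 mg/dL clause is applied over the full 14-day window, not the strict
48-hour KDIGO form — this matches the mild-AKI definition the Motwani score
was developed against.  Urine-output criteria and AKI beyond 14 days are out
of scope.  A patient with no in-window creatinine and no RRT raises an
"unassessable" error rather than silently labelling.

## Risk scores

Both scores are implemented from their published point tables.  Continuous
predictors bin by the printed edges read inclusively: a printed range such as
dose "101–150 mg" is the half-open interval (100, 150], so off-grid values
(dose 100.5, hemoglobin 11.95) always land in exactly one bin — this is
property-tested across randomized inputs.  Albumin and hemoglobin are
treated as g/dL (the point-table header prints mg/dL, but the accompanying
cohort descriptives and clinical plausibility make g/dL unambiguous).  The
enumerated score maxima are 9.5 (Motwani) and 22.5 (Gupta).  The Gupta
magnesium item (1 point when < 2.0 mg/dL) can be excluded for the
sensitivity variant; excluding it changes the score by exactly 0 or 1 point.

The Motwani score maps to probability in closed form:
`odds(s) = (0.04/0.96) · 1.49^s`.  The Gupta simple score has no published
per-score probabilities; its development study used a cubic-spline model
whose coefficients are not public.  The mapper slot is therefore pluggable.
The default is a logistic regression on a restricted cubic spline of the
score with 4 knots at the {5, 35, 65, 95}% score quantiles (standard
Harrell-style practice), fitted on a *reference* cohort generated with
development-population prevalences (severe 5.2%, C-AKI 13.6%, n = 5,000)
rather than the validation cohort.  Fitting the mapper on a higher-risk
reference population is what makes the pre-recalibration curves behave like
a genuinely external model: applied to the local cohort it overestimates
severe risk (CITL < 0) and underestimates the commoner mild outcome
(CITL > 0), mirroring the directions seen in external validation.  Published
spline coefficients can be dropped in through the same mapper interface.

## Synthetic cohort generator

The generator emulates the *statistical structure* of a single-centre
Japanese cisplatin cohort (n = 1,684), not its patients:

* **Continuous covariates** are log-normal with the published medians and
  log-scale spread solved from the published IQRs (dose 110 [90–130] mg;
  creatinine 0.75 [0.63–0.87] mg/dL; albumin 3.9, hemoglobin 12.5, WBC 5.99,
  platelets 256, magnesium 2.05 with their IQRs).  Age uses a truncated
  skew-normal on [18, 95] (skew −8, location 76.21, scale 15.70), solved
  once to match median 66 and IQR 58–71; the fit reproduces all three
  quantiles to < 0.6%.
* **Binary covariates** use the published rates (male 66.7%, hypertension
  35.3%, diabetes 12.1%, smoker 64.8%).  Covariates are independent except
  a positive age–hypertension association (log-odds +0.55 per decade, with
  the intercept solved to preserve the marginal rate); the source cohort
  publishes no correlation structure, so nothing else is coupled.
* **Outcomes are sampled truth-first.**  Both scores are computed
  noiselessly on the complete covariates; C-AKI is Bernoulli with
  logit p = a₁ + 0.10·Gupta + 0.12·Motwani, and severe C-AKI is sampled
  among C-AKI patients from logit p = a₂ + 0.28·Gupta − 0.28·Motwani.  The
  intercepts are solved by root-finding so the configured prevalences
  (11.0% and 2.1%) hold in expectation; the per-point weights are frozen
  constants solved once, offline, so that the *post-imputation* scores
  discriminate at the published level (Gupta AUROC ≈ 0.616 for C-AKI and
  ≈ 0.674 for severe; Motwani ≈ 0.613 / ≈ 0.594).  A configurable
  miscalibration drift (intercept shift, slope multiplier on the logit
  scale) is available for experiments; it defaults to neutral because the
  fixed published mappers are already miscalibrated against this truth
  process in the externally-observed directions.
* **Trajectories** are synthesized *after* the class is drawn: one baseline
  plus post-treatment creatinine at days 3, 7 and 14, with the day-7 peak
  placed by inverting the threshold rules with uniform jitter strictly
  inside the class-consistent interval (non-events below
  min(1.5·b, b + 0.3); stage 1 between that threshold and 2·b; severe above
  2·b unless RRT carries the label).  This makes the generator→label round
  trip exact for every patient and any seed, which the suite asserts.
  RRT is assigned only within the severe class (rate 0.10 given severe —
  the source publishes no RRT count, so this is a fixed plausible choice).
* **Missingness** is applied as a separate masking step at the published
  rates (magnesium 61.2%, albumin 6.0%, WBC 0.7%, platelets 0.1%),
  missing-completely-at-random by default.  An optional MAR mode tilts the
  mask probability with age (+0.4 log-odds per decade, marginal rate
  preserved) as a stress test for the imputer; the source states a
  missing-at-random assumption but publishes no mechanism.

What the generator does **not** emulate: repeat treatment cycles or
time-varying dosing, the eligibility cascade of a real EHR extraction,
inter-lab correlations, seasonal/temporal drift, or creatinine assay
differences.  Passing tests therefore demonstrate that the *machinery* is
correct under a realistic data-generating process, not that the published
models perform identically on any particular real population.

## Imputation

Single deterministic regression imputation, as is common before applying a
points-based score: for each lab with missing entries, OLS of the lab on the
always-complete covariates (age, sex, dose, baseline creatinine,
hypertension, diabetes, smoking) over complete cases; missing cells get the
conditional mean, clipped to a positive floor (0.01).  No stochastic
residual draws and no Rubin pooling — the imputed values feed coarse score
bins, and conditional-mean imputation keeps the pipeline seed-free at this
stage.  Outcome labels are deliberately excluded from the predictor set to
avoid leakage.  Fitting refuses a lab with fewer complete cases than
predictors + 2 and warns below 20.

## Validation metrics and bootstrap

AUROC is the mid-rank Mann–Whitney estimator (ties 0.5), exactly equal to
the O(n²) pairwise-concordance oracle and invariant to strictly increasing
transforms of the predictions.  Calibration-in-the-large is the intercept of
an offset-logistic fit (slope on logit p̂ fixed at 1); the calibration slope
is the free coefficient in an unconstrained logistic refit — the standard
Steyerberg definitions; negative CITL means systematic overestimation.
Probabilities are clipped to [1e-9, 1 − 1e-9] before logit, with a warning.

These one- and two-parameter fits are solved by a damped Newton (IRLS)
routine inside the package because bootstrap and coverage loops need on the
order of 10⁵ such fits per run; the solver is cross-checked against
statsmodels to 1e-6 in the test suite.  Separation and non-convergence raise
typed errors; inside the bootstrap they downgrade to NaN replicates so a
degenerate (e.g. perfect) predictor still yields its AUROC estimate.

Bootstrap inference resamples patients with replacement, unstratified,
n_boot = 1,000 by default; replicates with single-class outcomes are redrawn
and counted.  Reported point estimates are bootstrap means and intervals are
percentile 2.5/97.5 bounds.  AUROC differences use the paired patient-level
bootstrap with two-sided p = 2·min(P(Δ ≤ 0), P(Δ ≥ 0)), floored at
1/n_boot.  Calibration plots use ten equal-count risk groups (ties kept
together, merged with a warning when the prediction distribution supports
fewer distinct quantiles) and a lowess smoother with span 0.75.

## Recalibration

Logistic recalibration refits only an intercept and a slope, regressing the
outcome on the **raw score** (not on the logit of the mapped probability —
for the Motwani model the two are affinely equivalent; for the spline-mapped
Gupta model they are not, and the raw-score convention is the one the
validation literature states).  On the fitting cohort the refit identities
CITL = 0 and slope = 1 hold to machine precision, and AUROC is unchanged
whenever the fitted slope is positive.  The default report bootstraps the
metrics of the once-fitted recalibration (apparent validation); refitting
inside each replicate is a one-line variant left to the caller since the
default matches how such tables are usually produced.  Only these two
parameters are ever updated — no structural revision.

## Decision curves

Net benefit uses the inclusive rule treat-if p̂ ≥ t over a default grid
0.005–0.50 in steps of 0.005.  Treat-all and treat-none references are
always emitted; `net_harm_regions` flags thresholds where a strategy's net
benefit is negative.  Closed-form identities (perfect predictor → NB = π;
treat-all crossing zero at t = π) are asserted to 1e-12.

## Pipeline conventions and problem sizes

All intermediates are plain CSV/TSV/JSON; floats serialize at full precision
(`repr`) so a fixed configuration and seed reproduce every artifact
byte-for-byte — for this reason the run manifest stores artifact paths
relative to the output directory and no wall-clock timestamps.  Stage
boundaries log patient and event counts.  No multiplicity correction is
applied to comparison p-values (α = 0.05, raw).

Test problem sizes are chosen to make each check sharp at desk scale:
marginal/prevalence recovery at n = 50,000 (3% / 3 binomial SE tolerances),
recalibration parameter recovery at n = 50,000 (±0.05), slope-CI coverage
over 200 generator seeds at n = 600 with 250-replicate bootstraps, and the
null calibration of the AUROC comparison over 500 simulations.  The
reference cohort for the Gupta mapper uses n = 5,000, large enough that
spline-fit noise is negligible relative to the validation cohort's sampling
error.

## Known limitations

* Covariate independence (beyond age–hypertension) understates real-world
  confounding between labs, dose and comorbidity.
* The trajectory model is three fixed sampling days with a day-7 peak; real
  surveillance is irregular and the peak day varies.
* Conditional-mean imputation slightly attenuates between-patient variance;
  with 61% missing magnesium the imputed Gupta magnesium item is nearly
  constant, which is faithful to how a real cohort with that missingness
  behaves but means the magnesium item contributes little observable signal.
* The Gupta default mapper is a refit stand-in for unpublished development
  coefficients; absolute pre-recalibration Gupta probabilities are therefore
  reference-cohort-dependent, though the recalibrated results are not.
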