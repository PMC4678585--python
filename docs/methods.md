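# Methods

This note documents the models behind `periopcea`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate, and
the numerical conventions. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The evaluation in one paragraph

A two-arm randomised trial compares cardiac output-guided haemodynamic
therapy with usual care in high-risk gastrointestinal surgery. Effectiveness
is measured in QALYs built from EQ-5D-3L assessments at randomisation, 30
days and 6 months; costs are 6-month NHS costs. The joint incremental effect
(ΔCost, ΔQALY) is estimated by covariate-adjusted regression with a site
random intercept, combined into the incremental net monetary benefit
INB(λ) = λ·ΔQALY − ΔCost, and summarised by acceptability curves and the
expected value of perfect information. Lifetime results extrapolate survivors
beyond the 6-month landmark with general-population life tables and
population utility norms, discounted at 3.5% per annum.

## QALY construction

* Utilities come from a decrement-based EQ-5D-3L value set
  (`index = 1 − constant·1{any>1} − Σ level decrements − N3·1{any=3}`).
  The bundled UK general-population time-trade-off tariff spans
  [−0.594, 1]; coefficients live in a versioned CSV
  (`data/uk_eq5d3l_tariff.csv`) and are never hard-coded, so any
  decrement-style tariff can be substituted.
* QALYs are the trapezoidal area under the utility-time curve over 0.5 years
  with assessments at 0, 1/12 and 1/2 years (1 month = 30.4375 days,
  6 months = 182.625 days, so the year fractions are exact).
* Base case anchoring: the curve starts at the **day-30** index value. The
  randomisation score is confounded by the acute surgical episode, so it
  serves as a regression covariate instead; a sensitivity re-anchors at the
  randomisation value. These are distinct roles and both are kept.
* Decedents: assessments after death score zero (base case). The
  interpolation sensitivity instead declines linearly from the last observed
  value to zero at the death date; for deaths before the 30-day assessment
  the interpolation starts from the randomisation value, the only observation
  that exists.
* Negative (worse-than-dead) utilities integrate negatively and are reported,
  not clipped.
* A missing utility needed by the curve yields a *flagged* trajectory, never
  a silent substitution; completion is the imputation stage's job. How to
  handle a missing day-30 anchor when the randomisation value is observed is
  genuinely open; imputation (which uses the randomisation value as a
  predictor) was chosen over deterministic substitution.

## Costing

* Procedure reference costs bundle the operation and an average stay, so the
  adjusted surgery cost subtracts `avg_los × ward-day rate + 1 recovery day`
  (floored at zero with a warning).
* Critical-care days are costed by level (2 and 3); the cardiac output
  monitor is costed once per patient whose record shows use, in either arm
  (intention-to-treat costing of actual resource use); dopexamine per mg;
  fluids and blood per ml, with intra-operative and post-operative volumes
  priced identically. Blood products are costed per ml by default because no
  per-unit convention is fixed; the rate is configurable.
* Sensitivity add-ons: `s1` adds one level-2 day plus one recovery-nurse hour
  for patients not transferred directly to critical care; `s2` adds 4.5 nurse
  hours per intervention-arm patient.
* The bundled `unit_costs_default.yaml` is a **synthetic placeholder**
  (2012–13 price-year layout): the national reference-cost and
  blood-service tables it stands in for are not redistributable. Any real
  analysis must supply its own table; every number that depends on unit costs
  in examples and tests is conditional on these placeholders.

## Six-month estimation

* Both outcomes are regressed on the same covariates — age, sex, urgency,
  surgical category, post-operative location, ASA grade, renal impairment,
  diabetes, cardio-respiratory risk, randomisation EQ-5D — plus treatment.
  With identical regressors, SUR point estimates equal per-equation least
  squares, and the covariance between the two treatment coefficients is
  `r·se_c·se_q` with `r` the residual cross-correlation.
* Site handling (`site_mode`): `random_intercept` (default; linear mixed
  model per equation, REML) with a fixed-intercept OLS fallback when the site
  variance is estimated on the zero boundary and the mixed-model covariance
  is singular; `fixed` (site dummies + cluster-robust SEs); `none`.
  The source analysis names a random site effect but not the estimator, so
  the estimator choice is exposed.
* Missing EQ-5D indices are completed by chained equations
  (`IterativeImputer`, Bayesian linear model with posterior sampling),
  predictors: arm, covariates, total cost and observed utilities. Imputed
  values are clipped to the tariff range. Death-structural absences are never
  imputed. `m = 20` imputations by default (standard practice; the source
  analysis does not state m). Per-imputation seeds derive from one master
  seed. With complete data the m chained copies are identical, so pooling
  reduces exactly to the single complete-data fit and the pipeline takes that
  shortcut.
* Rubin's rules pool points (mean) and covariance
  (`within-mean + (1+1/m)·between`).
* The CEAC uses the bivariate-normal approximation `Φ(INB/SE)` by default,
  consistent with the normal-INB assumption used downstream for EVPI; a
  within-site patient bootstrap (`bootstrap_ceac`) is available as a skew
  check. Subgroups (urgency, surgical category, first-ten-per-site vs later
  recruits) reuse the global imputations and subset them — refitting the
  imputation model inside small subgroups would be unstable; this is
  switchable by passing subgroup-specific completed tables.

## Lifetime extrapolation

* Survivors at the 6-month landmark are projected in annual cycles. Base
  case: age-sex-matched life-table annual death probabilities, expressed as
  `qx × SMR` with SMR = 1 — the standardised-mortality-ratio form makes
  excess-mortality scenarios and the parametric sensitivity live in one code
  path. The multiplicative (rather than additive) form of excess mortality
  was an open choice; multiplicative SMR is the field's convention.
* Parametric sensitivity: exponential, Weibull, Gompertz, log-normal and
  log-logistic families are fitted to the trial's censored survival data by
  maximum likelihood (lifelines, plus a direct Gompertz MLE) and compared by
  AIC (= 2k − 2ℓ); `select_model` also reports each family's predicted annual
  death rates against the life table at the cohort's age-sex mix, because an
  extrapolation predicting *lower* mortality than the general population for
  high-risk surgical patients is implausible on its face. The selection is
  surfaced, not silently automated; the projection default is population
  rates.
* Post-landmark utility: the arm's mean 6-month utility up to year 1, linear
  interpolation to the age-matched population norm across years 1–2, norms
  thereafter; or frozen at the 6-month mean (sensitivity). The 6-month mean
  is computed per arm from the data (pooling is an option).
* Discounting at 3.5%/year starts at the landmark; within-trial QALYs are
  undiscounted. Annual cycles with half-cycle correction by default (neither
  is dictated by the source; both are configurable).
* No costs are modelled beyond 6 months, so lifetime ΔCost equals the
  6-month ΔCost.
* The bundled life table and utility norms are **synthetic placeholders**
  generated by code (Gompertz–Makeham hazards; a linear utility decline with
  age) sized to resemble UK older-age values; real analyses should supply
  national tables as CSV.

## Value of information

Under INB ~ N(mean, sd²), EVPI per patient is the unit-normal loss
`sd·[φ(z) − z·Φ(−z)]`, `z = |mean|/sd`. CI-to-SD conversion uses 1.959964.
The effective population is either supplied directly (a published
hospital-statistics total is consumed as given, since whether it is pre- or
post-discounting is unstated) or derived as `Σ incidence/(1+r)^(t−1)` over
the horizon.

## Synthetic-trial generator

The generator is the package's test bed and defines the study conditions:

* n = 2×367 patients in 17 sites; covariate mix matched to the trial's
  baseline table (age ~ truncated normal 71.7 (8.5) on [50, 99], 64% male,
  3.5% non-elective, the observed surgical-category/ASA/post-operative
  location mix).
* Deaths: exponential within the 6-month window per arm, calibrated to
  6-month mortality (0.076, 0.115). Mortality is not covariate-dependent — a
  deliberate simplification; only the arm-level proportion is anchored.
* Utilities: latent AR(1) trivariate normal per patient (SD 0.28,
  autocorrelation 0.5) plus a site intercept (SD 0.05) and centred covariate
  effects, clipped to [−0.594, 1]. Both arms share the randomisation mean;
  follow-up means default to the observed survivor levels (0.66/0.63 at 30
  days, 0.73/0.71 at 6 months).
* Costs: gamma with additive mean
  (`usual-care mean 8974 + arm effect + centred covariate effects + site
  intercept`, shape 1.55 ≈ the observed SD/mean ratio). The additive-mean
  (rather than log-link) parameterisation was chosen so the design's
  `true_delta_cost` *is* the exact marginal arm difference.
* Exact QALY truth: the intervention's latent utility shift is solved by root
  finding against the closed-form censored-normal mean so that the implied
  mean QALY difference — including the differential-mortality contribution
  under the day-30-anchored weights (7/24 on the 30-day utility given
  survival to day 30, 5/24 on the 6-month utility given survival) — equals
  `true_delta_qaly` exactly, conditional on the realised covariates.
  `ground_truth()` is therefore an exact echo of the design.
* Missingness: logistic MAR in ASA grade, urgency and arm among survivors,
  with the intercept solved to hit the marginal rates (15%/15%); masking uses
  its own random substream so the same dataset can be regenerated unmasked
  for MAR checks. Component-level cost SDs are not anchored anywhere, so
  resource-use draws are calibrated to the published resource table
  marginals and the *total* cost SD only.

What the generator does **not** emulate: informative missingness, mortality
that depends on covariates or utilities, correlation between cost and QALY at
the patient level (they are generated independently, so cross-equation
correlation tests a null), per-day cost trajectories, or the physiology of
the haemodynamic algorithm. Passing tests therefore demonstrate that the
estimation machinery is correct under the stated data-generating assumptions,
not that those assumptions hold in any real dataset.

## Numerical conventions and degenerate inputs

* QALY trapezoids agree with fine-grid integration to 1e−9 on
  piecewise-linear curves (asserted).
* Zero INB variance makes the CEAC a 0/1 step with a warning; sd = 0 gives
  EVPI 0; λ = 0 gives INB = −ΔCost.
* AIC ties are broken by the fixed family order (exponential, Weibull,
  Gompertz, log-normal, log-logistic) and flagged.
* Survival projection stops at the life table's terminal age (qx = 1
  enforced); a request beyond the table raises an error naming the age.
* Rank-deficient design matrices raise an error listing the collinear terms;
  constant columns (e.g. a subgroup's own factor) are dropped automatically.
* Currency is reported to the nearest £1 and QALYs to 3 decimals in the
  report bundle.

## Problem sizes used in the test suite

The parameter-recovery study runs 500 replicates of the full trial size
(n = 734) with complete follow-up, checking unbiasedness of ΔCost and ΔQALY
against the generator's exact truth and 93–97% coverage of the 95% INB
interval. Oracle equivalence checks use 10⁵ draws (CEAC) and up to 10⁶ draws
(EVPI). These sizes give Monte-Carlo error comfortably below the asserted
tolerances.

## Known limitations

* Normal-theory CIs on a skewed cost distribution undercover slightly at
  n = 734 (the coverage band in the acceptance suite reflects this).
* The cluster-robust `fixed` mode relies on ~17 clusters, few enough that
  its SEs are themselves noisy.
* The bundled tariff is the only value-set family supported (additive
  decrements); crosswalks from other instruments are out of scope.
* Lifetime SDs of projected QALYs depend strongly on the placeholder life
  table and norms and are not comparable to published values.
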