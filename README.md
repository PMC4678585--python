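# periopcea

Trial-based cost-effectiveness analysis of peri-operative, cardiac
output-guided haemodynamic therapy versus usual care in high-risk patients
undergoing major gastrointestinal surgery — built as a reusable, tested
Python pipeline from patient-level trial records to 6-month and lifetime
cost-effectiveness, acceptability curves and value of information.

The package is aimed at health economists and trial statisticians who want a
transparent, scriptable implementation of a within-trial economic evaluation:

* **QALYs** from EQ-5D-3L profiles at randomisation, 30 days and 6 months via
  a pluggable value set (the UK general-population tariff is bundled), using
  the area-under-the-curve method: `QALY = ∫ u(t) dt` over the half-year
  window, anchored at the day-30 utility in the base case, with decedents
  assigned zero utility at post-death assessments.
* **Costs** from resource use (critical-care and ward days, monitoring,
  dopexamine, fluids and blood products) plus national reference costs for
  the procedure, with the embedded average stay and one recovery day
  subtracted to avoid double counting.
* **Incremental estimates** from a covariate-adjusted bivariate regression of
  costs and QALYs with a random intercept per site; with identical regressors
  the seemingly-unrelated-regression point estimates equal per-equation least
  squares, and the cross-equation covariance comes from the residual
  correlation. Missing EQ-5D data are completed by chained-equation multiple
  imputation and pooled by Rubin's rules.
* **Decision measures**: incremental net monetary benefit
  `INB(λ) = λ·ΔQALY − ΔCost`, cost-effectiveness acceptability curves
  `P(INB(λ) > 0)` over £0–£50,000/QALY, lifetime extrapolation with life-table
  mortality and 3.5% discounting, and expected value of perfect information
  `EVPI = σ·[φ(z) − z·Φ(−z)]` with `z = |INB|/σ`.

Because the original patient-level data are not deposited, the package ships
a first-class synthetic-trial generator (`periopcea.synthetic`) that emulates
the trial's statistical structure — two arms of 367 patients in 17 sites,
6-month mortality near 7.6% vs 11.5%, right-skewed gamma costs, AR(1)
correlated utilities, site effects, MAR missingness — with *exactly known*
incremental cost and QALY, so every stage is testable end to end.

## Worked example

```python
from periopcea import TrialDesign, generate_trial
from periopcea.cea import sixmonth_cea, inb, ceac
from periopcea.lifetime import lifetime_cea
from periopcea.voi import evpi

trial = generate_trial(TrialDesign(seed=42))          # 734 synthetic patients
est, completed = sixmonth_cea(trial, m=20, seed=1)    # impute, fit, pool
print(inb(est))                                       # 6-month INB at £20k/QALY

est_lt, curve, models = lifetime_cea(trial, completed=completed)
mean, se, ci = inb(est_lt)
print(mean, ci, evpi(mean, inb_sd=se, population=270503).evpi_per_patient)
```

prints (seed 42):

```
6-month:  ΔCost −£367, ΔQALY 0.013, INB £625 (95% CI −£479 to £1,729)
lifetime: ΔCost −£367, ΔQALY 0.306, INB £6,487 (95% CI −£976 to £13,949)
P(cost-effective at £20,000/QALY) = 0.96;  EVPI £69/patient, £18.7M for 270,503 patients
```

Read: on this synthetic replicate the intervention saves money and gains
QALYs on average, but the CI on the net benefit crosses zero; the
acceptability curve and EVPI quantify the residual decision uncertainty.
(The generator's true effects are ΔCost = −£400 and ΔQALY = 0.01; a single
trial of n = 734 estimates them with the sampling noise shown.)

The same pipeline is scriptable from the shell:

```bash
periopcea simulate --seed 7 --out trial.csv
periopcea qaly --trial trial.csv --out qaly.csv
periopcea cost --trial trial.csv --out costs.csv
periopcea run  --seed 7 --outdir outputs/      # full bundle incl. sensitivity analyses
```

`periopcea run` writes arm summaries, CEAC grids, the subgroup table
(urgency, surgical category, early vs late recruitment), the six sensitivity
scenarios (extra nursing/critical-care costs, randomisation-anchored
utilities, decedent interpolation, frozen post-6-month quality of life,
parametric extrapolation) and the EVPI JSON, all reproducible bit-for-bit
from one master seed.

## Layout

| module | contents |
|---|---|
| `periopcea.synthetic` | trial design, generator, exact ground truth |
| `periopcea.eq5d` | EQ-5D-3L profiles, value sets, QALY area under the curve |
| `periopcea.costing` | unit-cost tables, per-patient cost breakdowns |
| `periopcea.cea` | imputation, bivariate regression, Rubin pooling, INB, CEAC, subgroups |
| `periopcea.lifetime` | parametric survival fits, life-table projection, lifetime CEA |
| `periopcea.voi` | EVPI and effective-population calculations |
| `periopcea.report` / `periopcea.cli` | orchestration and the `periopcea` command |

See `docs/methods.md` for the modelling assumptions, defaults and known
limitations.
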