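# ldh-pipeline

Modelling and prediction of pain relief under physical therapy for lumbar
disc herniation, as a tested, reusable Python pipeline.

Patients with lumbar disc herniation rate their pain on the visual analogue
scale (VAS, 0–10) before each of ten physical-therapy sessions. Three
clinical questions drive the pipeline:

1. **Can the course of relief be expressed mathematically?** Each patient's
   trajectory is fit with a decreasing logistic curve between fixed
   asymptotes,

       y(x) = K / (1 + exp(a + b·x)),

   where the upper asymptote K is anchored by the minimal clinically
   significant difference (MCSD) of the VAS — K = VAS₁ + 1.2, capped at 10
   when VAS₁ ≥ 8.8 — and (a, b) encode onset and descent rate, estimated by
   bounded least squares. Fit quality is summarized per patient and by a
   pooled global R².
2. **How early can the final outcome be predicted?** The curve is refit on
   only the first m = 2..9 sessions and extrapolated to session 10. Each
   truncated model is scored by the MCSD rule: *effectiveness* (does the
   predicted whole-course decline > 1.2 points agree with the observed
   one?) and *remission magnitude* (is the predicted final score within
   1.2 points of the measured one?). Success rates per course length are
   tabulated and compared with pooled chi-square tests.
3. **Do baseline characteristics predict efficacy?** A from-scratch
   least-squares gradient boosting machine (F₀ = 0, residuals fit by
   depth-limited regression trees with shrinkage μ; the tuned setting is
   1000 trees, μ = 0.1, depth 4, sqrt feature subsampling) classifies a
   binary efficacy outcome from 14 covariates on a seeded 7:3 train/test
   split, evaluated by ROC: AUC with a DeLong 95% CI, and the
   Youden-optimal sensitivity/specificity.

The original cohort (142 patients) is not publicly deposited, so the package
includes a first-class synthetic-cohort generator that reproduces the
structure of the data — baseline VAS median 6.8 on [3, 10], heterogeneous
S-shaped and near-linear remission curves, 0.1-resolution scores with small
additive noise, and a covariate table with a configurable logistic outcome
link. Every downstream stage is exercised and tested against that generator;
see `docs/methods.md` for the model details and for what the simulation does
and does not emulate.

## Worked example

```python
from ldh_pipeline.synthetic_cohort import SimulationConfig, simulate_cohort
from ldh_pipeline.trajectory_model import fit_patient, r_squared_global
from ldh_pipeline.truncated_prediction import build_success_tables, pooled_group_comparison

cohort = simulate_cohort(SimulationConfig(seed=0))          # 142 patients
fits = [fit_patient(t) for t in cohort.trajectories]
print(f"global R^2: {r_squared_global(fits):.3f}")
f = fits[0]
print(f"patient {f.patient_id}: K={f.asymptotes.K:.1f}, a={f.a:.2f}, b={f.b:.2f}, R^2={f.r2:.3f}")

eff, rem = build_success_tables(cohort.trajectories)
print(f"effectiveness success at m=2: {eff.success_percent(2)}%  at m=9: {eff.success_percent(9)}%")
cmp_ = pooled_group_comparison(eff, [[2, 3, 4], [5, 6, 7, 8, 9]])
print(f"pooled {{2-4}} vs {{5-9}}: chi2={cmp_.chi2:.2f}, p={cmp_.p:.2g}")
```

prints

```
global R^2: 0.987
patient P001: K=8.7, a=-2.43, b=0.65, R^2=0.993
effectiveness success at m=2: 88.0%  at m=9: 99.3%
pooled {2-4} vs {5-9}: chi2=21.26, p=4e-06
```

Reading the output: the pooled R² of 0.987 says the logistic curve explains
essentially all the variance of the (simulated, lightly noisy) trajectories.
Patient P001's asymptote sits 1.2 points above their first score (K = 8.7),
with inflection at −a/b ≈ 3.7 sessions and a descent rate of 0.65 per
session. Predictions from only the first two sessions classify effectiveness
correctly for 88% of patients, rising to 99.3% with nine sessions, and the
pooled comparison confirms that predictions based on five or more sessions
are significantly more reliable than earlier ones — the qualitative pattern
the truncation analysis is designed to expose.

The same run, end to end with all output files and a plain-text report:

```
ldh-pipeline all --seed 0 --out results/
```

which writes `trajectories.csv`, `covariates.csv`, `truth.json`, `fits.csv`,
`predictions.csv`, `success_tables.csv`, `comparisons.json`, `model.json`,
`importance.csv`, `scores.csv`, `roc.json`, `roc_curve.csv` and `report.txt`.
Individual stages are available as `ldh-pipeline simulate|fit|
predict-truncated|gbm-train|evaluate`; runs are byte-for-byte reproducible
given the two seeds recorded in the report header.

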