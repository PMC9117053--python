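# Methods

## The remission-curve model

Pain under a 10-session course of physical therapy is recorded before each
session on the visual analogue scale (VAS, 0–10). The course of one patient's
pain is modelled as a decreasing logistic curve between two asymptotes:

    y(x) = lower + H / (1 + exp(a + b·x)),    H = K − lower,  b ≥ 0,

with x the session index 1..10. The curve has three interpretable pieces:

* **K, the upper asymptote** — the pain level relief decays *from*. It is not
  estimated. Following the minimal clinically significant difference (MCSD)
  of the VAS scale, 1.2 points, K is anchored 1.2 points above the
  first-session score and capped at the scale maximum: K = VAS₁ + 1.2 for
  VAS₁ < 8.8, otherwise K = 10. The rationale is that a patient's
  pre-treatment plateau cannot be distinguished from their first rating by
  less than the smallest clinically meaningful difference.
* **lower, the lower asymptote** — the residual pain floor, pinned at 0
  (complete relief) by default. `FitOptions(fit_lower=True)` frees it in
  [0, K] for sensitivity analysis.
* **a and b** — onset and rate. The inflection (half-relief point) sits at
  x* = −a/b; b is the per-session descent rate. These two are estimated per
  patient by bounded nonlinear least squares.

With both asymptotes fixed, the fit is a 2-parameter problem solved with the
trust-region-reflective method (`scipy.optimize.least_squares`), bounds
a ∈ [−50, 50], b ∈ [0, 10], tolerances 1e-10, at most 1000 function
evaluations. Initialization is deterministic: b₀ = 0.5 and a₀ = −b₀·x_mid,
where x_mid is the session whose observed score is nearest the half-relief
level (5.5 for a constant series). The optimizer never returns a point worse
than the initialization; non-convergence returns the best iterate flagged
`converged=False`. The curve is evaluated through the logistic sigmoid, so
extreme exponents saturate at the asymptotes instead of overflowing.

Goodness of fit is reported two ways: per patient, R² = 1 − SS_res/SS_tot
about the patient's own mean (undefined for a constant series), and globally
by pooling the residual and total sums of squares over all patients before
dividing. The pooled definition was chosen over the mean of per-patient R²
because a "global" coefficient most naturally weights patients by their
variability; both are computable from the per-patient output.

## Truncated-course prediction and MCSD scoring

To ask how early the final outcome can be predicted, the curve is refitted on
the first m = 2..9 sessions only (the asymptote still anchored on the first
score) and extrapolated to session 10, clipping to [0, 10]. Each truncated
model is scored twice:

* **Effectiveness success** — "clinically effective" means a whole-course VAS
  decline of strictly more than 1.2 points. The decline is measured from the
  first *observed* score for both the predicted and the actual final value
  (the first measurement is what anchors the asymptote). The truncated model
  succeeds when its classification matches the observed one.
* **Remission-magnitude success** — the predicted final score lies within 1.2
  points of the measured final score, inclusive. (A 1e-9 guard keeps
  differences that are exactly 1.2 on the 0.1-resolution scale on the success
  side despite binary floating point.)

The boundary conventions — strict for effectiveness, inclusive for remission —
follow the clinical definitions exactly as worded. Success counts per course
length are tabulated with percentages printed to one decimal, rounding halves
up. Differences across lengths use Pearson chi-square tests without
continuity correction (counts are large); after a significant omnibus test,
lengths are pooled into clinically motivated groups ({2–4} vs {5–9} for
effectiveness; {2–4}, {5–7}, {8–9} for remission magnitude, with consecutive
pairwise follow-ups) to limit multiple comparisons. A pairwise table that is
degenerate (two all-success groups) is skipped rather than failing the run.
Patients without a complete 10-session course are excluded with a warning;
non-converged truncated fits contribute their best iterate so row sums stay
at the cohort size.

## The gradient boosting machine

Efficacy is also predicted from 14 baseline covariates with a from-scratch
forward-stagewise least-squares boosting machine:

    F₀(x) = 0,  rᵢ = yᵢ;  for m = 1..M:  F_m = F_{m−1} + μ·f̂_m,  r ← r − μ·f̂_m

with y the binary outcome encoded 0/1 and f̂_m a CART-style regression tree
fit to the current residuals. The algorithm is implemented literally on the
0/1 labels — squared-error loss, zero initialization — and scores are clipped
to [0, 1] when used as probabilities. This is deliberate: the procedure is
the plain least-squares recipe even though the outcome is binary. A
`loss="logistic"` mode (pseudo-residuals y − σ(F), scores mapped through the
sigmoid) is available for comparison but is not the default.

Trees are grown greedily to `max_depth`: each split maximizes the reduction
in residual SSE, candidate thresholds are midpoints between consecutive
sorted distinct feature values, and leaf values are the mean residual of the
leaf's samples. Determinism: gain ties break toward the lower feature index,
then the lower threshold; the only randomness is the per-split feature
subsample (`max_features="sqrt"`) and optional row subsampling, both driven
by one generator seeded with `random_state`. Feature importance is the total
split gain credited to each feature over all trees, normalized to sum to 1,
ties ranked by feature index.

Default hyperparameters are the tuned clinical setting: M = 1000 trees,
μ = 0.1, depth 4, min_samples_split 2, min_samples_leaf 1, subsample 1,
sqrt feature subsampling, random_state 10. Data are split 7:3 into train and
test by a seeded uniform permutation (first ⌈0.7·n⌉ shuffled rows train).

Algebraic invariants maintained (and tested): F₀ = 0 exactly; stored
residuals equal y − F_m(X) after every iteration; the final prediction is
exactly the sum of the shrunken trees; training SSE is non-increasing for
μ ∈ (0, 1] (each leaf-mean tree step reduces SSE by (2μ − μ²)·Σf̂² ≥ 0).

## ROC evaluation

The ROC curve is computed by exact threshold enumeration (one point per
distinct score, "positive" meaning score ≥ threshold, plus the (0,0)
endpoint). AUC is the trapezoidal area, which equals the Mann-Whitney
concordance probability with ties counted one half. The 95% confidence
interval uses DeLong's placement-value variance by default, with a seeded
percentile bootstrap (2000 resamples) as fallback when a class has fewer
than two samples, and as a cross-check. The operating point maximizes
Youden's J = sensitivity + specificity − 1, ties resolved to the lower
threshold. An optional comparator scores the same split with a
maximum-likelihood logistic regression (statsmodels), falling back to an
L2-regularized fit under quasi-separation.

## The synthetic cohort

No patient-level data accompany the clinical analysis, so the pipeline is
exercised on a simulator that reproduces the structure the analysis assumes.
Per patient:

1. a baseline score vas₁ is drawn from a normal(6.8, 1.8) truncated to
   [3, 10] — matching the reported median 6.8 and range 3.0–10.0;
2. a descent rate b is drawn lognormally with median 0.7 (log-sd 0.5),
   giving both steep and slow responders;
3. the latent curve is anchored so that it passes exactly through vas₁ at
   session 1 *and* its asymptote obeys the MCSD rule (K = vas₁ + 1.2, capped
   at 10). This fixes the onset: x* = 1 + ln(vas₁/(K − vas₁))/b. The
   anchoring makes the generator self-consistent with the fitting stage — on
   noise-free data the default fit recovers (a, b) exactly — and spreads the
   inflection across and beyond the session window, so the cohort contains
   both clearly S-shaped and near-linear trajectories. Setting
   `anchor_baseline=False` instead draws the onset uniformly from
   `onset_range` and rescales the asymptote onto the baseline (capped at 10),
   sacrificing rule-consistency.
4. observations are curve values plus additive Gaussian noise (sd 0.3,
   small relative to the 1.2-point MCSD), clipped to [0, 10] and rounded to
   0.1 — the resolution of a ruler on a 10 cm line;
5. fourteen covariates are drawn (protrusion sagittal diameter in mm,
   two 1–5 degeneration grades, age from a truncated normal matching the
   reported 53.1 ± 15.2 on [17, 87], symptom-to-treatment months, and nine
   generic standard-normal columns), and a binary efficacy outcome follows a
   Bernoulli draw with logit = 0.9 + Σβ·z on standardized covariates. The
   default coefficients make larger protrusions, heavier degeneration, older
   age and longer untreated symptoms reduce the odds of good efficacy
   (≈62% prevalence); the link and coefficients are recorded in truth.json.

What the simulator does **not** emulate: dropout or missing sessions (the
clinical cohort completed all ten), any coupling between the covariate layer
and the trajectory layer (the efficacy label is a function of covariates
only), floor/ceiling response behaviour beyond clipping, serially correlated
measurement error, and the real cohort's covariate correlations. Passing
tests therefore demonstrate the *machinery* — recovery, scoring, ranking,
calibration of the arithmetic — not the clinical effect sizes; headline
real-data values (global R² 0.721, AUC 0.936, the importance top-five) are
not reproducible from simulation and are not targets.

## Problem sizes and numerical choices

Tests run on deliberately small instances: 142-patient default cohorts
(the reference size), 200 noise-free patients for parameter recovery,
2000 patients for distributional Monte-Carlo checks, 20 trajectories for the
grid-search equivalence, a 50×3 dataset for reference-implementation
agreement, and 25–50 boosting iterations wherever the full M = 1000 is not
the point. The dense (a, b) grid-search oracle zooms an 81×81 grid 40 times
with an 8-cell re-centre window, which tracks the narrow ridge created by
the correlated (a, b) pair down to ~1e-10 in SSE. Per-patient R² is declared
undefined when SS_tot ≤ 1e-12; percentages round halves up to one decimal;
all VAS predictions are clipped to [0, 10] before scoring.

## Known limitations

* The literal least-squares GBM on 0/1 labels is not a calibrated
  probabilistic classifier; clipped scores are adequate for ROC ranking but
  should not be read as probabilities.
* With the tuned 1000×depth-4 setting on ~100 training rows the ensemble
  interpolates its training data; test-set AUC on the default synthetic
  cohort is correspondingly modest (~0.67 in the worked example). This is a
  property of the configuration at simulated effect sizes, not of the
  implementation.
* Exact split-gain ties (common when residuals take few distinct values)
  are broken by a fixed deterministic rule; other implementations may pick
  different, equally optimal trees, after which boosting paths diverge.
* The DeLong interval is asymptotic; at very small n it can touch the
  clipped bounds 0/1, where the bootstrap cross-check is more informative.
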