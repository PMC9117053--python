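"""Synthetic cohorts of physical-therapy pain trajectories and covariates.

No patient-level data are deposited for the clinical cohort this pipeline
analyses, so every downstream stage is exercised on simulated patients that
reproduce the structure the analysis assumes:

* a baseline (first-session) VAS distribution with median near 6.8 and
  range within [3, 10];
* heterogeneous logistic remission curves — some clearly S-shaped within
  the 10-session window, some with the inflection beyond it and therefore
  near-linear over the observed sessions;
* small additive measurement noise and ruler-resolution rounding (0.1);
* a 14-column covariate table whose binary efficacy outcome follows a
  logistic link with configurable coefficients.

Each patient's latent curve is ``y(x) = K / (1 + exp(a + b*x))`` with the
descent rate ``b`` drawn lognormally. By default the curve is anchored so
that it passes exactly through the drawn baseline score at session 1 *and*
its upper asymptote equals the MCSD rule value (baseline + 1.2, capped at
10). That makes the generator self-consistent with the fitting stage: on
noise-free data the per-patient fit recovers (a, b) exactly. The onset of
relief (the inflection x* = -a/b) is then determined by the baseline and
the rate, x* = 1 + ln(vas1 / (K - vas1)) / b, and spans both the inside
and the outside of the session window. Setting ``anchor_baseline=False``
instead draws the onset uniformly from ``onset_range`` and rescales the
asymptote to hit the baseline, sacrificing the MCSD-rule consistency.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .errors import ConfigurationError
from .trajectory_model import (
    MCSD,
    VAS_MAX,
    VasTrajectory,
    compute_upper_asymptote,
)

__all__ = [
    "N_SESSIONS",
    "COVARIATE_NAMES",
    "DEFAULT_COVARIATE_EFFECTS",
    "SimulationConfig",
    "SyntheticPatient",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_covariates",
    "true_outcome_label",
    "inflection_session",
    "curve_linearity",
]

#: Sessions per treatment course; pain is rated before each session.
N_SESSIONS = 10

#: The five predictors named by the clinical analysis plus nine generic ones.
COVARIATE_NAMES = (
    "protrusion_sagittal_diameter_mm",
    "surgical_segment_degeneration_grade",
    "age_years",
    "symptom_to_treatment_months",
    "adjacent_segment_degeneration_grade",
    "covariate_06",
    "covariate_07",
    "covariate_08",
    "covariate_09",
    "covariate_10",
    "covariate_11",
    "covariate_12",
    "covariate_13",
    "covariate_14",
)

# (location, scale) used to standardize each covariate inside the outcome
# link, fixed at the generating distribution's approximate moments.
_COVARIATE_STANDARDIZATION = (
    (6.0, 2.0),
    (3.0, 1.2),
    (53.1, 15.2),
    (8.0, 6.0),
    (2.6, 1.1),
    (0.0, 1.0),
    (0.0, 1.0),
    (0.0, 1.0),
    (0.0, 1.0),
    (0.0, 1.0),
    (0.0, 1.0),
    (0.0, 1.0),
    (0.0, 1.0),
    (0.0, 1.0),
)

#: Default outcome-link coefficients: larger protrusions, heavier segment
#: degeneration, older age and longer untreated symptoms reduce the odds of
#: good efficacy; the nine generic covariates are pure noise.
DEFAULT_COVARIATE_EFFECTS = (
    -1.6,
    -1.1,
    -0.9,
    -0.7,
    -0.55,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; the defaults define the reference study conditions."""

    n_patients: int = 142
    vas1_mean: float = 6.8
    vas1_sd: float = 1.8
    vas1_range: tuple[float, float] = (3.0, 10.0)
    onset_range: tuple[float, float] = (2.0, 8.0)
    rate_log_mean: float = math.log(0.7)
    rate_log_sd: float = 0.5
    noise_sd: float = 0.3
    rounding: float = 0.1
    covariate_effects: tuple[float, ...] = DEFAULT_COVARIATE_EFFECTS
    outcome_intercept: float = 0.9
    anchor_baseline: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "vas1_range", tuple(self.vas1_range))
        object.__setattr__(self, "onset_range", tuple(self.onset_range))
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        lo, hi = self.vas1_range
        if not (0.0 <= lo < hi <= VAS_MAX):
            raise ConfigurationError("vas1_range must be an increasing pair in [0, 10]")
        if self.vas1_sd <= 0:
            raise ConfigurationError("vas1_sd must be positive")
        olo, ohi = self.onset_range
        if not olo < ohi:
            raise ConfigurationError("onset_range must be an increasing pair")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.rounding < 0:
            raise ConfigurationError("rounding must be >= 0")
        if len(self.covariate_effects) != len(COVARIATE_NAMES):
            raise ConfigurationError(
                f"covariate_effects must have {len(COVARIATE_NAMES)} entries, "
                f"got {len(self.covariate_effects)}"
            )
        object.__setattr__(self, "covariate_effects", tuple(float(c) for c in self.covariate_effects))


@dataclass
class SyntheticPatient:
    """One simulated patient: latent curve, observed trajectory, covariates."""

    trajectory: VasTrajectory
    true_params: tuple[float, float, float]  # (K, a, b)
    covariates: dict[str, float]
    true_outcome: int  # covariate-link efficacy label (GBM target)
    outcome_prob: float

    @property
    def patient_id(self) -> str:
        return self.trajectory.patient_id

    def noise_free_curve(self, sessions=None) -> np.ndarray:
        """Latent curve values at the requested sessions (default: observed)."""
        k, a, b = self.true_params
        x = self.trajectory.sessions if sessions is None else np.asarray(sessions)
        return k * expit(-(a + b * x.astype(float)))


@dataclass
class SyntheticCohort:
    patients: list[SyntheticPatient]
    config: SimulationConfig
    link: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def trajectories(self) -> list[VasTrajectory]:
        return [p.trajectory for p in self.patients]

    def trajectories_frame(self) -> pd.DataFrame:
        rows = [
            (p.patient_id, int(s), float(v))
            for p in self.patients
            for s, v in zip(p.trajectory.sessions, p.trajectory.vas)
        ]
        return pd.DataFrame(rows, columns=["patient_id", "session", "vas"])

    def covariates_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            row = {"patient_id": p.patient_id}
            row.update(p.covariates)
            row["outcome"] = p.true_outcome
            rows.append(row)
        return pd.DataFrame(rows)

    def truth(self) -> dict:
        return {
            "link": self.link,
            "patients": {
                p.patient_id: {
                    "K": p.true_params[0],
                    "a": p.true_params[1],
                    "b": p.true_params[2],
                    "inflection": inflection_session(p.true_params),
                    "outcome_prob": p.outcome_prob,
                    "true_outcome": p.true_outcome,
                    "curve_effective": true_outcome_label(p),
                }
                for p in self.patients
            },
        }

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write trajectories.csv, covariates.csv and truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "trajectories": out / "trajectories.csv",
            "covariates": out / "covariates.csv",
            "truth": out / "truth.json",
        }
        self.trajectories_frame().to_csv(paths["trajectories"], index=False)
        self.covariates_frame().to_csv(paths["covariates"], index=False)
        paths["truth"].write_text(json.dumps(self.truth(), indent=1, sort_keys=True))
        return paths


def _draw_baseline(config: SimulationConfig, rng: np.random.Generator) -> float:
    lo, hi = config.vas1_range
    alpha = (lo - config.vas1_mean) / config.vas1_sd
    beta = (hi - config.vas1_mean) / config.vas1_sd
    v = float(
        truncnorm.rvs(
            alpha, beta, loc=config.vas1_mean, scale=config.vas1_sd, random_state=rng
        )
    )
    # keep the baseline strictly below the scale maximum so the curve can
    # pass through it with a finite exponent
    return min(v, VAS_MAX - 1e-6)


def _draw_curve_params(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Draw one patient's latent (K, a, b)."""
    vas1 = _draw_baseline(config, rng)
    b = float(rng.lognormal(config.rate_log_mean, config.rate_log_sd))
    if config.anchor_baseline:
        # Asymptote follows the MCSD rule applied to the baseline; the onset
        # is then fixed by requiring curve(1) = vas1.
        k = compute_upper_asymptote(vas1)
        a = math.log(k / vas1 - 1.0) - b
    else:
        # Onset drawn uniformly; the asymptote is rescaled so that the curve
        # passes through the baseline, capped at the scale maximum.
        t_star = float(rng.uniform(*config.onset_range))
        a = -b * t_star
        k = vas1 * (1.0 + math.exp(min(a + b, 50.0)))
        k = min(k, VAS_MAX)
    return k, a, b


def simulate_covariates(
    patient_params: tuple[float, float, float] | None,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, float], int, float]:
    """Draw one patient's 14 covariates and the binary efficacy outcome.

    The outcome follows a Bernoulli draw with logit equal to
    ``intercept + sum(effects * z)`` where ``z`` are the covariates
    standardized by their generating moments. The curve parameters are not
    used: the covariate table is an independent prognostic layer, as in a
    baseline-predictors efficacy model.
    """
    if len(config.covariate_effects) != len(COVARIATE_NAMES):
        raise ConfigurationError("covariate_effects must have 14 entries")
    age_lo, age_hi = 17.0, 87.0
    values = {
        COVARIATE_NAMES[0]: float(np.clip(rng.normal(6.0, 2.0), 1.0, 14.0)),
        COVARIATE_NAMES[1]: int(rng.choice([1, 2, 3, 4, 5], p=[0.1, 0.2, 0.3, 0.25, 0.15])),
        COVARIATE_NAMES[2]: float(
            truncnorm.rvs(
                (age_lo - 53.1) / 15.2,
                (age_hi - 53.1) / 15.2,
                loc=53.1,
                scale=15.2,
                random_state=rng,
            )
        ),
        COVARIATE_NAMES[3]: float(rng.lognormal(math.log(6.0), 0.8)),
        COVARIATE_NAMES[4]: int(rng.choice([1, 2, 3, 4, 5], p=[0.2, 0.3, 0.3, 0.15, 0.05])),
    }
    for name in COVARIATE_NAMES[5:]:
        values[name] = float(rng.normal(0.0, 1.0))

    logit = config.outcome_intercept
    for name, (loc, scale), beta in zip(
        COVARIATE_NAMES, _COVARIATE_STANDARDIZATION, config.covariate_effects
    ):
        logit += beta * (values[name] - loc) / scale
    prob = float(expit(logit))
    outcome = int(rng.random() < prob)
    return values, outcome, prob


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Generate a full cohort: trajectories, latent parameters, covariates.

    Deterministic given ``config.seed``: one Generator drives every draw in
    a fixed per-patient order.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    width = max(3, len(str(config.n_patients)))
    sessions = np.arange(1, N_SESSIONS + 1)
    patients = []
    for i in range(config.n_patients):
        k, a, b = _draw_curve_params(config, rng)
        curve = k * expit(-(a + b * sessions.astype(float)))
        observed = curve.copy()
        if config.noise_sd > 0:
            observed = observed + rng.normal(0.0, config.noise_sd, size=N_SESSIONS)
        observed = np.clip(observed, 0.0, VAS_MAX)
        if config.rounding > 0:
            observed = np.round(observed / config.rounding) * config.rounding
            observed = np.clip(observed, 0.0, VAS_MAX)
        traj = VasTrajectory(f"P{i + 1:0{width}d}", sessions, observed)
        covariates, outcome, prob = simulate_covariates((k, a, b), config, rng)
        patients.append(
            SyntheticPatient(
                trajectory=traj,
                true_params=(k, a, b),
                covariates=covariates,
                true_outcome=outcome,
                outcome_prob=prob,
            )
        )
    link = {
        "type": "logistic",
        "intercept": config.outcome_intercept,
        "coefficients": dict(zip(COVARIATE_NAMES, config.covariate_effects)),
        "standardization": {
            name: {"loc": loc, "scale": scale}
            for name, (loc, scale) in zip(COVARIATE_NAMES, _COVARIATE_STANDARDIZATION)
        },
    }
    return SyntheticCohort(patients=patients, config=config, link=link)


def true_outcome_label(patient: SyntheticPatient) -> int:
    """Ground-truth curve-level efficacy: latent decline over the course > MCSD.

    A decline of exactly 1.2 does not qualify (strictly more than the MCSD).
    """
    start, end = patient.noise_free_curve(sessions=np.array([1, N_SESSIONS]))
    return int((start - end) > MCSD)


def inflection_session(true_params: tuple[float, float, float]) -> float:
    """Session at which the latent curve inflects (-a/b); inf for a flat curve."""
    _, a, b = true_params
    if b == 0:
        return math.inf
    return -a / b


def curve_linearity(true_params: tuple[float, float, float]) -> float:
    """R^2 of a straight-line fit to the latent curve over sessions 1..10.

    Values near 1 mean the trajectory is visually linear within the session
    window; lower values indicate a clear sigmoid. A constant curve returns 1.
    """
    k, a, b = true_params
    x = np.arange(1, N_SESSIONS + 1, dtype=float)
    y = k * expit(-(a + b * x))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 1e-15:
        return 1.0
    slope, intercept = np.polyfit(x, y, 1)
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    return 1.0 - ss_res / ss_tot
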