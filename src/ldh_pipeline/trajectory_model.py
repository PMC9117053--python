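"""Logistic remission-curve model for session-indexed VAS pain scores.

Pain relief over a course of physical-therapy sessions is modelled as a
decreasing logistic curve between two asymptotes,

    y(x) = lower + H / (1 + exp(a + b*x)),        H = K - lower,  b >= 0,

where ``x`` is the session index (1..10 for a full course), ``K`` is the
upper asymptote (the pain level the curve decays from), ``lower`` the lower
asymptote (0 by default: complete relief), ``a`` locates the inflection
(onset of relief at x* = -a/b) and ``b`` is the descent rate per session.

The upper asymptote is not estimated: it is anchored by the minimal
clinically significant difference (MCSD) of the VAS scale, 1.2 points.
``K`` is placed 1.2 points above the first-session score, capped at the
scale maximum of 10 (the cap engages once the first score is >= 8.8).
With both asymptotes fixed, only (a, b) are estimated per patient by
bounded nonlinear least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .errors import DomainError, InputError

__all__ = [
    "MCSD",
    "VAS_MAX",
    "K_CAP_THRESHOLD",
    "VasTrajectory",
    "AsymptoteSpec",
    "FitOptions",
    "CurveFit",
    "compute_upper_asymptote",
    "logistic_curve",
    "fit_patient",
    "r_squared_patient",
    "r_squared_global",
]

#: Minimal clinically significant difference of the VAS scale, in points.
MCSD = 1.2

#: Upper bound of the visual analogue scale.
VAS_MAX = 10.0

#: First-session score at or above which the upper asymptote saturates at VAS_MAX.
K_CAP_THRESHOLD = VAS_MAX - MCSD  # 8.8


@dataclass(frozen=True)
class VasTrajectory:
    """One patient's session-indexed VAS pain scores.

    Parameters
    ----------
    patient_id : str
        Identifier, carried through all outputs.
    sessions : ndarray of int
        Strictly increasing treatment time points (1..10 for a full course).
    vas : ndarray of float
        Pain scores in [0, 10], one per session.
    """

    patient_id: str
    sessions: np.ndarray
    vas: np.ndarray

    def __post_init__(self) -> None:
        sessions = np.asarray(self.sessions, dtype=int)
        vas = np.asarray(self.vas, dtype=float)
        object.__setattr__(self, "sessions", sessions)
        object.__setattr__(self, "vas", vas)
        if sessions.ndim != 1 or vas.ndim != 1 or len(sessions) != len(vas):
            raise InputError("sessions and vas must be 1-D arrays of equal length")
        if len(sessions) < 2:
            raise InputError("a trajectory needs at least two sessions")
        if np.any(np.diff(sessions) <= 0):
            raise InputError("sessions must be strictly increasing")
        if np.any((vas < 0.0) | (vas > VAS_MAX)):
            raise InputError("VAS scores must lie in [0, 10]")

    def __len__(self) -> int:
        return len(self.sessions)

    def truncated(self, m: int) -> "VasTrajectory":
        """First ``m`` sessions as a new trajectory."""
        if m < 2:
            raise InputError("a truncated trajectory needs at least two sessions")
        if m > len(self):
            raise InputError(
                f"cannot truncate to {m} sessions: only {len(self)} available"
            )
        return VasTrajectory(self.patient_id, self.sessions[:m], self.vas[:m])


@dataclass(frozen=True)
class AsymptoteSpec:
    """Upper/lower asymptotes of the remission curve; H is the gap between them."""

    K: float
    lower: float = 0.0

    def __post_init__(self) -> None:
        if not (self.lower <= self.K <= VAS_MAX):
            raise DomainError(
                f"asymptotes must satisfy lower <= K <= {VAS_MAX}; "
                f"got lower={self.lower}, K={self.K}"
            )

    @property
    def H(self) -> float:
        """Maximum possible relief: distance between the asymptotes."""
        return self.K - self.lower


@dataclass(frozen=True)
class FitOptions:
    """Controls for the per-patient least-squares fit.

    ``k`` overrides the MCSD asymptote rule with an explicit upper asymptote
    (used e.g. when the generating asymptote of simulated data is known).
    ``fit_lower`` frees the lower asymptote as a third parameter in [0, K]
    for sensitivity analyses; by default it is pinned at 0.
    """

    k: float | None = None
    fit_lower: bool = False
    a_bounds: tuple[float, float] = (-50.0, 50.0)
    b_bounds: tuple[float, float] = (0.0, 10.0)
    b_init: float = 0.5
    tol: float = 1e-10
    max_nfev: int = 1000


def compute_upper_asymptote(vas1: float) -> float:
    """Upper asymptote K implied by the first-session VAS score.

    K = vas1 + 1.2 (the MCSD), saturating at the scale maximum 10 when the
    first score is at or above 8.8.
    """
    if not 0.0 <= vas1 <= VAS_MAX:
        raise DomainError(f"first VAS score must lie in [0, 10]; got {vas1}")
    if vas1 >= K_CAP_THRESHOLD:
        return VAS_MAX
    return vas1 + MCSD


def logistic_curve(x, spec: AsymptoteSpec, a: float, b: float):
    """Decreasing logistic curve ``lower + H / (1 + exp(a + b*x))``.

    Evaluated through the logistic sigmoid, so extreme exponents saturate at
    the asymptotes instead of overflowing. Scalar in, scalar out; array in,
    array out.
    """
    x = np.asarray(x, dtype=float)
    out = spec.lower + spec.H * expit(-(a + b * x))
    return float(out) if out.ndim == 0 else out


@dataclass
class CurveFit:
    """Result of fitting the remission curve to one trajectory."""

    patient_id: str
    asymptotes: AsymptoteSpec
    a: float
    b: float
    sessions: np.ndarray
    observed: np.ndarray
    fitted: np.ndarray = field(repr=False, default=None)
    converged: bool = True
    n_params: int = 2

    def __post_init__(self) -> None:
        if self.fitted is None:
            self.fitted = logistic_curve(self.sessions, self.asymptotes, self.a, self.b)

    @property
    def residuals(self) -> np.ndarray:
        return self.observed - self.fitted

    @property
    def sse(self) -> float:
        return float(np.sum(self.residuals**2))

    @property
    def ss_tot(self) -> float:
        return float(np.sum((self.observed - self.observed.mean()) ** 2))

    @property
    def n_obs(self) -> int:
        return len(self.sessions)

    @property
    def exact_fit(self) -> bool:
        """True when observations do not exceed the free parameters (m = 2)."""
        return self.n_obs <= self.n_params

    @property
    def r2(self) -> float | None:
        return r_squared_patient(self)

    def predict(self, x) -> np.ndarray:
        return logistic_curve(x, self.asymptotes, self.a, self.b)


def _initial_point(traj: VasTrajectory, spec: AsymptoteSpec, options: FitOptions):
    """Deterministic initialization: b0 fixed, a0 = -b0 * x_mid.

    x_mid is the session whose observed score is nearest the half-relief
    level (lower + H/2); for a constant series every session is equally
    informative and the midpoint of a 10-session course (5.5) is used.
    """
    half = spec.lower + spec.H / 2.0
    if np.ptp(traj.vas) == 0.0:
        x_mid = 5.5
    else:
        x_mid = float(traj.sessions[int(np.argmin(np.abs(traj.vas - half)))])
    b0 = options.b_init
    a0 = float(np.clip(-b0 * x_mid, *options.a_bounds))
    return a0, b0


def fit_patient(traj: VasTrajectory, options: FitOptions | None = None) -> CurveFit:
    """Fit (a, b) by bounded least squares with the asymptotes held fixed.

    The upper asymptote comes from :func:`compute_upper_asymptote` applied to
    the first observed score unless ``options.k`` overrides it. The optimizer
    (trust-region reflective) never increases the objective relative to the
    deterministic initialization; on non-convergence the best iterate is
    returned with ``converged=False``.
    """
    options = options or FitOptions()
    if len(traj) < 2:  # defensive; the type already enforces this
        raise InputError("fit requires at least two observations")
    k = options.k if options.k is not None else compute_upper_asymptote(traj.vas[0])
    x = traj.sessions.astype(float)
    y = traj.vas

    if options.fit_lower:
        spec0 = AsymptoteSpec(K=k, lower=0.0)

        def resid(p):
            return y - (p[2] + (k - p[2]) * expit(-(p[0] + p[1] * x)))

        a0, b0 = _initial_point(traj, spec0, options)
        lb = [options.a_bounds[0], options.b_bounds[0], 0.0]
        ub = [options.a_bounds[1], options.b_bounds[1], k]
        x0 = [a0, b0, 0.0]
    else:
        spec0 = AsymptoteSpec(K=k, lower=0.0)

        def resid(p):
            return y - spec0.H * expit(-(p[0] + p[1] * x))

        a0, b0 = _initial_point(traj, spec0, options)
        lb = [options.a_bounds[0], options.b_bounds[0]]
        ub = [options.a_bounds[1], options.b_bounds[1]]
        x0 = [a0, b0]

    res = least_squares(
        resid,
        x0,
        bounds=(lb, ub),
        method="trf",
        xtol=options.tol,
        ftol=options.tol,
        gtol=options.tol,
        max_nfev=options.max_nfev,
    )
    lower = float(res.x[2]) if options.fit_lower else 0.0
    spec = AsymptoteSpec(K=k, lower=lower)
    return CurveFit(
        patient_id=traj.patient_id,
        asymptotes=spec,
        a=float(res.x[0]),
        b=float(res.x[1]),
        sessions=traj.sessions,
        observed=y,
        converged=bool(res.status > 0),
        n_params=3 if options.fit_lower else 2,
    )


def r_squared_patient(fit: CurveFit) -> float | None:
    """Per-patient coefficient of determination, 1 - SS_res/SS_tot.

    Undefined (None) for a constant observed series, whose total sum of
    squares is zero.
    """
    ss_tot = fit.ss_tot
    if ss_tot <= 1e-12:
        return None
    return 1.0 - fit.sse / ss_tot


def r_squared_global(fits: list[CurveFit]) -> float:
    """Global coefficient of determination pooled over patients.

    Residual and total sums of squares are summed across all patients before
    forming 1 - sum(SS_res)/sum(SS_tot) (not the mean of per-patient values).
    """
    if not fits:
        raise InputError("r_squared_global needs at least one fit")
    ss_res = math.fsum(f.sse for f in fits)
    ss_tot = math.fsum(f.ss_tot for f in fits)
    if ss_tot <= 0.0:
        raise InputError("global R^2 undefined: every observed series is constant")
    return 1.0 - ss_res / ss_tot
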