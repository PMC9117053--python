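"""Efficacy prediction from truncated treatment courses.

For each patient the remission curve is refitted using only the first
m = 2..9 sessions and extrapolated to the final (10th) session. Two
clinical scores, both driven by the 1.2-point minimal clinically
significant difference (MCSD), grade each truncated model:

* *effectiveness success* — the truncated model classifies the patient the
  same way the observed course does, where "clinically effective" means a
  VAS decline of strictly more than 1.2 points from the first session to
  the last;
* *remission success* — the predicted final VAS lies within 1.2 points of
  the measured final VAS (inclusive).

Success counts per treatment length are tabulated and compared across
lengths with Pearson chi-square tests; when an omnibus test over all
lengths is significant, lengths are pooled into clinically motivated
groups (e.g. {2-4} vs {5-9}) and re-tested to limit multiple comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy.stats import chi2_contingency

from .errors import ConfigurationError, DegenerateTableError, InputError
from .synthetic_cohort import N_SESSIONS
from .trajectory_model import (
    MCSD,
    VAS_MAX,
    CurveFit,
    FitOptions,
    VasTrajectory,
    fit_patient,
)

__all__ = [
    "PredictionRecord",
    "SuccessTable",
    "PooledComparison",
    "fit_truncated",
    "predict_final_vas",
    "classify_effectiveness",
    "remission_success",
    "truncated_predictions",
    "build_success_tables",
    "chi_square_test",
    "pooled_group_comparison",
    "format_percent",
]

logger = logging.getLogger(__name__)

DEFAULT_LENGTHS = tuple(range(2, N_SESSIONS))  # 2..9


def fit_truncated(
    traj: VasTrajectory, m: int, options: FitOptions | None = None
) -> CurveFit:
    """Fit the remission curve to sessions 1..m only.

    The upper asymptote is still anchored on the (full-rule) first-session
    score, so truncation changes only the data entering the least-squares
    objective.
    """
    if m < 2:
        raise InputError("truncated fits need m >= 2 sessions")
    if m > len(traj):
        raise InputError(f"m={m} exceeds the {len(traj)} available sessions")
    return fit_patient(traj.truncated(m), options)


def predict_final_vas(fit: CurveFit, final_session: int = N_SESSIONS) -> float:
    """Curve value extrapolated to the final session, clipped to the VAS scale."""
    return float(np.clip(fit.predict(final_session), 0.0, VAS_MAX))


def classify_effectiveness(decline: float, mcsd: float = MCSD) -> bool:
    """Clinically effective iff the whole-course VAS decline exceeds the MCSD.

    The boundary is strict: a decline of exactly 1.2 points is not effective.
    """
    return decline > mcsd


def remission_success(
    predicted_final: float, actual_final: float, mcsd: float = MCSD
) -> bool:
    """Remission-magnitude success: |predicted - actual| within the MCSD (inclusive).

    A one-in-a-billion guard keeps differences that are exactly the MCSD on
    the 0.1-resolution VAS scale (e.g. |4.0 - 5.2|) on the success side
    despite binary floating-point representation.
    """
    return abs(predicted_final - actual_final) <= mcsd + 1e-9


@dataclass(frozen=True)
class PredictionRecord:
    """One patient x treatment-length prediction and its two success flags."""

    patient_id: str
    m: int
    predicted_final: float
    actual_final: float
    predicted_decline: float
    actual_decline: float
    effective_pred: bool
    effective_actual: bool
    converged: bool

    @property
    def effectiveness_success(self) -> bool:
        return self.effective_pred == self.effective_actual

    @property
    def remission_success(self) -> bool:
        return remission_success(self.predicted_final, self.actual_final)


def format_percent(count: int, total: int) -> float:
    """Percentage to one decimal place, rounding halves up (table convention)."""
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class SuccessTable:
    """Success/failure counts per treatment length m."""

    counts: dict[int, tuple[int, int]]  # m -> (successes, failures)
    n_patients: int

    def __post_init__(self) -> None:
        for m, (s, f) in self.counts.items():
            if s + f != self.n_patients:
                raise InputError(
                    f"row m={m}: {s} + {f} != n_patients = {self.n_patients}"
                )

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(sorted(self.counts))

    def success_percent(self, m: int) -> float:
        return format_percent(self.counts[m][0], self.n_patients)

    def failure_percent(self, m: int) -> float:
        return format_percent(self.counts[m][1], self.n_patients)

    def rows(self) -> list[tuple[int, int, float, int, float]]:
        """(m, successes, success %, failures, failure %) per length."""
        return [
            (m, s, self.success_percent(m), f, self.failure_percent(m))
            for m, (s, f) in sorted(self.counts.items())
        ]


def truncated_predictions(
    trajectories: list[VasTrajectory],
    lengths: tuple[int, ...] = DEFAULT_LENGTHS,
    options: FitOptions | None = None,
    mcsd: float = MCSD,
) -> list[PredictionRecord]:
    """Per patient x length prediction records.

    Patients without a complete course (all sessions up to the final one)
    are excluded with a warning. Declines, both predicted and actual, are
    measured from the first *observed* score, which also anchors the
    asymptote. Non-converged truncated fits still contribute via their best
    iterate so every length retains the full cohort.
    """
    records: list[PredictionRecord] = []
    for traj in trajectories:
        if len(traj) < N_SESSIONS:
            logger.warning(
                "patient %s excluded: %d of %d sessions observed",
                traj.patient_id,
                len(traj),
                N_SESSIONS,
            )
            continue
        first = float(traj.vas[0])
        actual_final = float(traj.vas[-1])
        actual_decline = first - actual_final
        effective_actual = classify_effectiveness(actual_decline, mcsd)
        for m in lengths:
            fit = fit_truncated(traj, m, options)
            predicted_final = predict_final_vas(fit)
            predicted_decline = first - predicted_final
            records.append(
                PredictionRecord(
                    patient_id=traj.patient_id,
                    m=m,
                    predicted_final=predicted_final,
                    actual_final=actual_final,
                    predicted_decline=predicted_decline,
                    actual_decline=actual_decline,
                    effective_pred=classify_effectiveness(predicted_decline, mcsd),
                    effective_actual=effective_actual,
                    converged=fit.converged,
                )
            )
    return records


def build_success_tables(
    trajectories: list[VasTrajectory] | None = None,
    lengths: tuple[int, ...] = DEFAULT_LENGTHS,
    options: FitOptions | None = None,
    mcsd: float = MCSD,
    records: list[PredictionRecord] | None = None,
) -> tuple[SuccessTable, SuccessTable]:
    """(effectiveness, remission) success tables over the given lengths.

    Either raw trajectories or precomputed prediction records may be given;
    records take precedence so the expensive truncated fits run once.
    """
    if records is None:
        if trajectories is None:
            raise InputError("either trajectories or records must be provided")
        records = truncated_predictions(trajectories, lengths, options, mcsd)
    by_m: dict[int, list[PredictionRecord]] = {}
    for rec in records:
        by_m.setdefault(rec.m, []).append(rec)
    if not by_m:
        raise InputError("no complete trajectories to tabulate")
    n = len({rec.patient_id for rec in records})
    eff_counts, rem_counts = {}, {}
    for m, recs in by_m.items():
        if len(recs) != n:
            raise InputError(f"length m={m} has {len(recs)} records for {n} patients")
        e = sum(r.effectiveness_success for r in recs)
        r_ = sum(r.remission_success for r in recs)
        eff_counts[m] = (e, n - e)
        rem_counts[m] = (r_, n - r_)
    return SuccessTable(eff_counts, n), SuccessTable(rem_counts, n)


def chi_square_test(contingency) -> tuple[float, int, float]:
    """Pearson chi-square on a groups x 2 count table, no continuity correction."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] != 2:
        raise InputError("contingency must be a (>=2) x 2 table")
    if np.any(table < 0):
        raise InputError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateTableError(
            "chi-square undefined: a row or column marginal is zero"
        )
    chi2, p, dof, _ = chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


@dataclass
class PooledComparison:
    """Chi-square comparison of success rates across pooled length groups."""

    grouping: tuple[tuple[int, ...], ...]
    contingency: np.ndarray
    chi2: float
    df: int
    p: float
    pairwise: list["PooledComparison"] = field(default_factory=list)

    def group_labels(self) -> list[str]:
        return ["-".join(map(str, g)) for g in self.grouping]


def pooled_group_comparison(
    table: SuccessTable, grouping: list[list[int]]
) -> PooledComparison:
    """Pool treatment lengths into groups and chi-square the pooled table.

    ``grouping`` must partition the table's lengths into at least two
    groups. With three or more groups, pairwise 2x2 comparisons between
    consecutive groups are attached (the follow-up tests run after a
    significant omnibus result); a degenerate pair (e.g. two all-success
    groups, which leave a zero column marginal) is skipped.
    """
    groups = tuple(tuple(sorted(g)) for g in grouping)
    flat = [m for g in groups for m in g]
    if len(groups) < 2:
        raise ConfigurationError("grouping must contain at least two groups")
    if sorted(flat) != sorted(table.lengths) or len(set(flat)) != len(flat):
        raise ConfigurationError(
            f"grouping {groups} is not a partition of lengths {table.lengths}"
        )
    contingency = np.array(
        [
            [
                sum(table.counts[m][0] for m in g),
                sum(table.counts[m][1] for m in g),
            ]
            for g in groups
        ],
        dtype=float,
    )
    chi2, df, p = chi_square_test(contingency)
    comparison = PooledComparison(groups, contingency, chi2, df, p)
    if len(groups) >= 3:
        for g1, g2 in zip(groups[:-1], groups[1:]):
            sub = contingency[[groups.index(g1), groups.index(g2)], :]
            try:
                c2, d, pv = chi_square_test(sub)
            except DegenerateTableError:
                logger.info("pairwise %s vs %s skipped: degenerate table", g1, g2)
                continue
            comparison.pairwise.append(
                PooledComparison((g1, g2), sub, c2, d, pv)
            )
    return comparison
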