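"""ROC analysis of classifier scores.

Implements the receiver-operating-characteristic curve, the trapezoidal
AUC (identical to the Mann-Whitney concordance probability with ties
counted one half), a DeLong variance-based confidence interval with a
seeded-bootstrap fallback, and the Youden-optimal operating point
(J = sensitivity + specificity - 1). Higher scores mean "predicted good
efficacy"; a sample is called positive when its score is at or above the
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import InputError

__all__ = [
    "RocResult",
    "roc_curve",
    "auc",
    "auc_confidence_interval",
    "youden_index",
    "optimal_operating_point",
    "evaluate_scores",
    "logistic_baseline_scores",
]


@dataclass
class RocResult:
    """ROC points and, once computed, the summary statistics.

    ``thresholds`` are in decreasing order, starting at +inf (no sample
    called positive: sensitivity 0, specificity 1) and ending at the lowest
    observed score (every sample positive: sensitivity 1, specificity 0).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float | None = None
    ci: tuple[float, float] | None = None
    operating_point: tuple[float, float, float] | None = None  # (thr, sens, spec)
    youden_j: float | None = None

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity

    @property
    def tpr(self) -> np.ndarray:
        return self.sensitivity


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if len(scores) != len(labels) or len(scores) == 0:
        raise InputError("scores and labels must be non-empty and matched")
    if not np.all(np.isin(labels, (0, 1))):
        raise InputError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise InputError("both classes must be present for ROC analysis")
    return scores, labels


def roc_curve(scores, labels) -> RocResult:
    """One ROC point per unique score threshold plus the (0,0) endpoint."""
    scores, labels = _validate(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s, lab = scores[order], labels[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(lab)[distinct]
    fp = np.cumsum(1 - lab)[distinct]
    n_pos, n_neg = int(labels.sum()), int(len(labels) - labels.sum())
    thresholds = np.r_[np.inf, s[distinct]]
    sens = np.r_[0.0, tp / n_pos]
    spec = np.r_[1.0, 1.0 - fp / n_neg]
    return RocResult(thresholds=thresholds, sensitivity=sens, specificity=spec)


def auc(roc: RocResult) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(roc.tpr, roc.fpr))


def _delong_variance(scores, labels) -> tuple[float, float]:
    """DeLong AUC and its variance from the placement values."""
    from scipy.stats import rankdata

    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = rankdata(pos)  # midranks within positives
    ty = rankdata(neg)
    tz = rankdata(np.r_[pos, neg])
    a = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # placement of each positive among negatives
    v10 = 1.0 - (tz[m:] - ty) / m
    s01 = v01.var(ddof=1) if m > 1 else np.nan
    s10 = v10.var(ddof=1) if n > 1 else np.nan
    return float(a), float(s01 / m + s10 / n)


def _bootstrap_ci(scores, labels, level, n_boot=2000, seed=0):
    rng = np.random.default_rng(seed)
    n = len(scores)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        lab = labels[idx]
        if lab.min() == lab.max():
            continue
        stats.append(auc(roc_curve(scores[idx], lab)))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def auc_confidence_interval(
    scores,
    labels,
    level: float = 0.95,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the AUC at the given level, clipped to [0, 1].

    The default is the DeLong asymptotic interval; ``method='bootstrap'``
    uses a seeded percentile bootstrap. When a class is too small for the
    DeLong variance (fewer than two samples), the bootstrap is used instead
    and a warning is emitted.
    """
    scores, labels = _validate(scores, labels)
    if not 0.0 <= level < 1.0:
        raise InputError("level must be in [0, 1)")
    if method == "bootstrap":
        return _bootstrap_ci(scores, labels, level, n_boot, seed)
    if method != "delong":
        raise InputError(f"unknown CI method {method!r}")
    a, var = _delong_variance(scores, labels)
    if not np.isfinite(var):
        warnings.warn(
            "class too small for the DeLong variance; falling back to bootstrap",
            stacklevel=2,
        )
        return _bootstrap_ci(scores, labels, level, n_boot, seed)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(np.clip(a - half, 0.0, 1.0)), float(np.clip(a + half, 0.0, 1.0))


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J statistic: sensitivity + specificity - 1."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise InputError("sensitivity and specificity must lie in [0, 1]")
    return sensitivity + specificity - 1.0


def optimal_operating_point(roc: RocResult) -> tuple[float, float, float, float]:
    """(threshold, sensitivity, specificity, J) maximizing Youden's J.

    Ties resolve to the lowest threshold among the maximizers.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(j == j.max())[-1]  # thresholds descend: last = lowest
    return (
        float(roc.thresholds[best]),
        float(roc.sensitivity[best]),
        float(roc.specificity[best]),
        float(j[best]),
    )


def evaluate_scores(
    scores, labels, level: float = 0.95, ci_seed: int = 0
) -> RocResult:
    """Full ROC evaluation: curve, AUC, CI and the Youden-optimal point."""
    roc = roc_curve(scores, labels)
    roc.auc = auc(roc)
    roc.ci = auc_confidence_interval(scores, labels, level=level, seed=ci_seed)
    thr, sens, spec, j = optimal_operating_point(roc)
    roc.operating_point = (thr, sens, spec)
    roc.youden_j = j
    return roc


def logistic_baseline_scores(X_train, y_train, X_test) -> np.ndarray:
    """Comparator classifier: maximum-likelihood logistic regression scores.

    Fitted with statsmodels on the training covariates; returns predicted
    probabilities for the test rows. Falls back to an L2-regularized fit if
    the unpenalized likelihood does not converge (e.g. quasi-separation).
    """
    import statsmodels.api as sm

    Xtr = sm.add_constant(np.asarray(X_train, dtype=float), has_constant="add")
    Xte = sm.add_constant(np.asarray(X_test, dtype=float), has_constant="add")
    y = np.asarray(y_train, dtype=float)
    model = sm.Logit(y, Xtr)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True) or not np.all(
            np.isfinite(res.params)
        ):
            raise ValueError("unconverged")
    except Exception:
        res = model.fit_regularized(alpha=1.0, disp=0, maxiter=500)
    return np.asarray(res.predict(Xte), dtype=float)
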