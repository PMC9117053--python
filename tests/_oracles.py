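"""Independent reference implementations used only to cross-check results.

Everything here is deliberately naive (dense grids, exhaustive enumeration,
pairwise loops) and shares no code with the package internals.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def grid_search_sse(
    x: np.ndarray,
    y: np.ndarray,
    k: float,
    a_bounds=(-50.0, 50.0),
    b_bounds=(0.0, 10.0),
    n_grid: int = 81,
    n_stages: int = 40,
    window: int = 8,
) -> float:
    """Minimum SSE of the fixed-asymptote logistic over a zooming (a, b) grid.

    Each stage lays a dense grid over the current box, then re-centres a box
    ``window`` cells wide on the best point. The generous window keeps the
    search from losing the narrow ridge the correlated (a, b) pair creates.
    """
    alo, ahi = a_bounds
    blo, bhi = b_bounds
    best = np.inf
    for _ in range(n_stages):
        aa = np.linspace(alo, ahi, n_grid)
        bb = np.linspace(blo, bhi, n_grid)
        pred = k * expit(-(aa[:, None, None] + bb[None, :, None] * x[None, None, :]))
        sse = ((y[None, None, :] - pred) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        best = min(best, float(sse[i, j]))
        da = (ahi - alo) / (n_grid - 1)
        db = (bhi - blo) / (n_grid - 1)
        alo = max(a_bounds[0], aa[i] - window * da)
        ahi = min(a_bounds[1], aa[i] + window * da)
        blo = max(b_bounds[0], bb[j] - window * db)
        bhi = min(b_bounds[1], bb[j] + window * db)
    return best


def concordance_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney concordance probability, ties counted one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def enumerate_roc_points(scores: np.ndarray, labels: np.ndarray):
    """All (threshold, sensitivity, specificity) by exhaustive thresholding."""
    points = [(np.inf, 0.0, 1.0)]
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    for thr in sorted(set(scores), reverse=True):
        called = scores >= thr
        tp = int(np.sum(called & (labels == 1)))
        tn = int(np.sum(~called & (labels == 0)))
        points.append((float(thr), tp / n_pos, tn / n_neg))
    return points


def pearson_chi2(table: np.ndarray) -> float:
    """Pearson statistic from the textbook expected-count formula."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    return float(((table - expected) ** 2 / expected).sum())


def best_split_bruteforce(x: np.ndarray, r: np.ndarray):
    """Best single split of one feature by trying every midpoint threshold."""
    values = np.sort(np.unique(x))
    parent = float(((r - r.mean()) ** 2).sum())
    best = None
    for lo, hi in zip(values[:-1], values[1:]):
        thr = (lo + hi) / 2.0
        left, right = r[x <= thr], r[x > thr]
        sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        gain = parent - float(sse)
        if best is None or gain > best[0]:
            best = (gain, thr, float(left.mean()), float(right.mean()))
    return best
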