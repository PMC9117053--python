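"""Least-squares gradient boosting with regression-tree base learners.

This is a from-scratch forward-stagewise boosting machine for a binary
efficacy outcome encoded 0/1, following the plain squared-error recipe:

    F_0(x) = 0,   r_i = y_i
    for m = 1..M:
        fit a depth-limited regression tree f_m to the residuals r
        F_m(x) = F_{m-1}(x) + mu * f_m(x)
        r_i   <- r_i - mu * f_m(x_i)
    F_M(x) = sum_m mu * f_m(x)

The base learner is a CART-style regression tree grown greedily: each
split maximizes the reduction in the residual sum of squares, thresholds
are midpoints between consecutive sorted unique feature values, and leaf
values are the mean residual of the samples they contain. Determinism is
guaranteed by breaking gain ties toward the lower feature index and the
lower threshold; the only randomness is the per-split feature subsampling
(``max_features='sqrt'``) and optional row subsampling, both driven by a
single seeded generator.

Scores are the raw additive predictions; for probabilistic use they are
clipped to [0, 1]. A ``loss='logistic'`` mode instead boosts the gradient
of the Bernoulli deviance (pseudo-residuals y - sigmoid(F)) and maps
scores through the sigmoid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, InputError

__all__ = [
    "GbmConfig",
    "RegressionTree",
    "GbmModel",
    "fit_regression_tree",
    "gbm_fit",
    "gbm_predict",
    "gbm_predict_proba",
    "feature_importance",
    "train_test_split",
]


@dataclass(frozen=True)
class GbmConfig:
    """Boosting hyperparameters; the defaults are the tuned clinical setting."""

    n_estimators: int = 1000
    learning_rate: float = 0.1
    max_depth: int = 4
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    subsample: float = 1.0
    max_features: str | int | None = "sqrt"
    random_state: int = 10
    loss: str = "squared_error"  # or "logistic"

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ConfigurationError("n_estimators must be >= 1")
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ConfigurationError("learning_rate must be in [0, 1]")
        if self.max_depth < 1:
            raise ConfigurationError("max_depth must be >= 1")
        if not 0.0 < self.subsample <= 1.0:
            raise ConfigurationError("subsample must be in (0, 1]")
        if self.loss not in ("squared_error", "logistic"):
            raise ConfigurationError(f"unknown loss {self.loss!r}")

    @property
    def max_leaves(self) -> int:
        """Terminal-node bound L implied by depth-limited growth (2^max_depth)."""
        return 2**self.max_depth

    def n_split_features(self, n_features: int) -> int:
        if self.max_features is None:
            return n_features
        if self.max_features == "sqrt":
            return max(1, int(math.sqrt(n_features)))
        if isinstance(self.max_features, int):
            if not 1 <= self.max_features <= n_features:
                raise ConfigurationError("max_features out of range")
            return self.max_features
        raise ConfigurationError(f"unsupported max_features {self.max_features!r}")


@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    value: float = 0.0
    gain: float = 0.0
    n_samples: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"value": self.value, "n": self.n_samples}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "gain": self.gain,
            "n": self.n_samples,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


def _best_split(X, r, feature_ids, min_samples_leaf):
    """Greedy SSE-reduction split over candidate features.

    Returns (gain, feature, threshold) or None. Thresholds are midpoints of
    consecutive distinct sorted values; ties in gain resolve to the lower
    feature index (features scanned in ascending order, strict improvement
    required) then the lower threshold (first argmax in sorted order).
    """
    n = len(r)
    total_sum = r.sum()
    total_sq = float(r @ r)
    parent_sse = total_sq - total_sum**2 / n
    best = None
    n_left = np.arange(1, n)
    n_right = n - n_left
    for f in sorted(feature_ids):
        col = X[:, f]
        order = np.argsort(col, kind="stable")
        cs = col[order]
        left_sum = np.cumsum(r[order])[:-1]
        valid = cs[1:] > cs[:-1]
        if min_samples_leaf > 1:
            valid = valid & (n_left >= min_samples_leaf) & (n_right >= min_samples_leaf)
        if not valid.any():
            continue
        children_sse = total_sq - left_sum**2 / n_left - (total_sum - left_sum) ** 2 / n_right
        gain = np.where(valid, parent_sse - children_sse, -np.inf)
        i = int(np.argmax(gain))
        if gain[i] > 1e-12 and (best is None or gain[i] > best[0]):
            best = (float(gain[i]), int(f), float((cs[i] + cs[i + 1]) / 2.0))
    return best


@dataclass
class RegressionTree:
    """Depth-limited CART regression tree; leaf values are residual means."""

    root: _Node
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X))
        stack = [(self.root, np.arange(len(X)))]
        while stack:
            node, idx = stack.pop()
            if node.is_leaf:
                out[idx] = node.value
                continue
            go_left = X[idx, node.feature] <= node.threshold
            stack.append((node.left, idx[go_left]))
            stack.append((node.right, idx[~go_left]))
        return out

    @property
    def n_leaves(self) -> int:
        count = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                count += 1
            else:
                stack.extend([node.left, node.right])
        return count

    def split_gains(self) -> dict[int, float]:
        """Total SSE reduction per feature over the tree's internal nodes."""
        gains: dict[int, float] = {}
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                gains[node.feature] = gains.get(node.feature, 0.0) + node.gain
                stack.extend([node.left, node.right])
        return gains

    def to_dict(self) -> dict:
        return self.root.to_dict()


def fit_regression_tree(
    X: np.ndarray,
    r: np.ndarray,
    config: GbmConfig | None = None,
    rng: np.random.Generator | None = None,
) -> RegressionTree:
    """Grow one regression tree on residual targets ``r``.

    At every split only a seeded random subset of features is scanned when
    ``max_features`` is restrictive; growth stops at ``max_depth``, at the
    minimum-sample rules, or when no split strictly reduces the SSE.
    """
    config = config or GbmConfig()
    X = np.asarray(X, dtype=float)
    r = np.asarray(r, dtype=float)
    if X.ndim != 2 or len(X) != len(r) or len(r) == 0:
        raise InputError("X must be 2-D with one target per row")
    rng = rng or np.random.default_rng(config.random_state)
    n_features = X.shape[1]
    k = config.n_split_features(n_features)

    def grow(idx: np.ndarray, depth: int) -> _Node:
        node = _Node(value=float(r[idx].mean()), n_samples=len(idx))
        if (
            depth >= config.max_depth
            or len(idx) < config.min_samples_split
            or len(idx) < 2 * config.min_samples_leaf
        ):
            return node
        if k < n_features:
            feature_ids = rng.choice(n_features, size=k, replace=False)
        else:
            feature_ids = np.arange(n_features)
        found = _best_split(X[idx], r[idx], feature_ids, config.min_samples_leaf)
        if found is None:
            return node
        node.gain, node.feature, node.threshold = found
        go_left = X[idx, node.feature] <= node.threshold
        node.left = grow(idx[go_left], depth + 1)
        node.right = grow(idx[~go_left], depth + 1)
        return node

    return RegressionTree(root=grow(np.arange(len(r)), 0), n_features=n_features)


@dataclass
class GbmModel:
    """Fitted boosting ensemble: F_0 = 0 plus M shrunken trees."""

    config: GbmConfig
    trees: list[RegressionTree]
    feature_names: list[str]
    training_loss_path: np.ndarray = field(repr=False, default=None)

    F0: float = 0.0

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_dict(self) -> dict:
        return {
            "F0": self.F0,
            "learning_rate": self.config.learning_rate,
            "loss": self.config.loss,
            "feature_names": self.feature_names,
            "trees": [t.to_dict() for t in self.trees],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        return X.to_numpy(dtype=float), names
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InputError("X must be a 2-D feature matrix")
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


def gbm_fit(X, y, config: GbmConfig | None = None) -> GbmModel:
    """Fit the boosting ensemble to binary outcomes encoded 0/1.

    The initial prediction is exactly 0 and residuals start at y, so after
    every iteration the stored residuals equal y minus the current model's
    training predictions (for squared-error loss). The training loss path
    records the SSE (or deviance) after each iteration.
    """
    config = config or GbmConfig()
    X, names = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != len(X) or len(y) == 0:
        raise InputError("X and y must be non-empty with matching rows")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise InputError("y must be binary, encoded 0/1")
    rng = np.random.default_rng(config.random_state)
    mu = config.learning_rate
    n = len(y)
    F = np.zeros(n)
    residuals = y.copy() if config.loss == "squared_error" else y - expit(F)
    trees: list[RegressionTree] = []
    loss_path = np.empty(config.n_estimators)
    for m in range(config.n_estimators):
        if config.subsample < 1.0:
            n_sub = max(1, int(round(config.subsample * n)))
            rows = rng.choice(n, size=n_sub, replace=False)
        else:
            rows = slice(None)
        tree = fit_regression_tree(X[rows], residuals[rows], config, rng)
        step = mu * tree.predict(X)
        F += step
        if config.loss == "squared_error":
            residuals -= step
            loss_path[m] = float(np.sum((y - F) ** 2))
        else:
            residuals = y - expit(F)
            p = expit(F)
            eps = 1e-12
            loss_path[m] = float(
                -2.0 * np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
            )
        trees.append(tree)
    return GbmModel(
        config=config, trees=trees, feature_names=names, training_loss_path=loss_path
    )


def gbm_predict(model: GbmModel, X) -> np.ndarray:
    """Raw additive score F_M(x) = sum_m mu * f_m(x)."""
    X, names = _as_matrix(X, model.feature_names)
    if X.shape[1] != model.n_features:
        raise InputError(
            f"feature count mismatch: model has {model.n_features}, X has {X.shape[1]}"
        )
    if isinstance(names, list) and names != model.feature_names and set(names) == set(
        model.feature_names
    ):
        raise InputError("feature columns are ordered differently from training")
    scores = np.full(len(X), model.F0, dtype=float)
    mu = model.config.learning_rate
    for tree in model.trees:
        scores += mu * tree.predict(X)
    return scores


def gbm_predict_proba(model: GbmModel, X) -> np.ndarray:
    """Probability of the positive class: clipped score (squared error) or sigmoid."""
    scores = gbm_predict(model, X)
    if model.config.loss == "logistic":
        return expit(scores)
    return np.clip(scores, 0.0, 1.0)


def feature_importance(model: GbmModel) -> list[tuple[str, float]]:
    """Features ranked by total split gain across all trees, normalized to sum 1.

    Ties rank by ascending feature index.
    """
    totals = np.zeros(model.n_features)
    for tree in model.trees:
        for f, g in tree.split_gains().items():
            totals[f] += g
    s = totals.sum()
    if s > 0:
        totals = totals / s
    order = sorted(range(model.n_features), key=lambda j: (-totals[j], j))
    return [(model.feature_names[j], float(totals[j])) for j in order]


def train_test_split(table: pd.DataFrame, ratio: float = 0.7, seed: int = 10):
    """Seeded uniform split: first ceil(ratio*n) shuffled rows train, rest test."""
    if not 0.0 < ratio < 1.0:
        raise InputError("ratio must be in (0, 1)")
    n = len(table)
    if n < 2:
        raise InputError("need at least two rows to split")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = math.ceil(ratio * n)
    return table.iloc[perm[:n_train]], table.iloc[perm[n_train:]]
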