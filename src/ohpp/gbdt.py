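"""A self-contained least-squares gradient-boosted regression-tree learner.

The ensemble starts from the training-target mean and stagewise adds
depth-limited, axis-aligned regression trees, each fit greedily to the
current residuals by exhaustive search over split points minimising the
squared error. Predictions are

    f(x) = initial + learning_rate * sum_t tree_t(x).

With learning_rate <= 1 and no row subsampling the training loss is
non-increasing in the number of trees; with learning_rate = 1, depth at
least log2(n) and min_samples_leaf = 1 the ensemble interpolates any finite
noiseless training set with distinct feature vectors.

Trees are stored as flat arrays (feature, threshold, children, value) so
batch prediction is vectorised — this matters because exact Shapley
attribution evaluates the model on millions of hybrid rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

try:  # jitted batch prediction; the numpy path below is the reference
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = ["GBDTParams", "GBDTEnsemble", "fit_gbdt"]


@dataclass(frozen=True)
class GBDTParams:
    n_trees: int = 300
    max_depth: int = 3
    learning_rate: float = 0.05
    min_samples_leaf: int = 5
    subsample: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_depth < 0 or self.min_samples_leaf < 1:
            raise ValueError("n_trees >= 1, max_depth >= 0, min_samples_leaf >= 1 required")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if not 0 < self.subsample <= 1:
            raise ValueError("subsample must be in (0, 1]")


class _Tree:
    """Flat-array regression tree: node i is a leaf iff feature[i] < 0."""

    __slots__ = ("feature", "threshold", "left", "right", "value")

    def __init__(self) -> None:
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[float] = []

    def _new_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(0.0)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(0.0)
        return len(self.feature) - 1

    def finalize(self) -> None:
        self.feature = np.asarray(self.feature, dtype=np.int32)
        self.threshold = np.asarray(self.threshold, dtype=np.float64)
        self.left = np.asarray(self.left, dtype=np.int32)
        self.right = np.asarray(self.right, dtype=np.int32)
        self.value = np.asarray(self.value, dtype=np.float64)

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(len(X), dtype=np.int32)
        feat = self.feature
        while True:
            f = feat[node]
            active = f >= 0
            if not active.any():
                break
            idx = np.where(active)[0]
            nd = node[idx]
            go_left = X[idx, f[idx]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.left[nd], self.right[nd])
        return self.value[node]


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int) -> tuple[int, float] | None:
    """Exhaustive greedy search for the SSE-minimising axis-aligned split."""
    n, m = X.shape
    if n < 2 * min_leaf:
        return None
    total_sum = y.sum()
    best_gain = 1e-12
    best: tuple[int, float] | None = None
    for j in range(m):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        csum = np.cumsum(ys)
        k = np.arange(1, n)  # left sizes
        valid = (xs[1:] > xs[:-1]) & (k >= min_leaf) & (n - k >= min_leaf)
        if not valid.any():
            continue
        left_sum = csum[:-1]
        # SSE reduction = sum_left^2/n_left + sum_right^2/n_right - total^2/n
        gain = left_sum**2 / k + (total_sum - left_sum) ** 2 / (n - k) - total_sum**2 / n
        gain = np.where(valid, gain, -np.inf)
        i = int(np.argmax(gain))
        if gain[i] > best_gain:
            best_gain = float(gain[i])
            best = (j, float((xs[i] + xs[i + 1]) / 2.0))
    return best


def _fit_tree(X: np.ndarray, y: np.ndarray, max_depth: int, min_leaf: int) -> _Tree:
    tree = _Tree()

    def grow(idx: np.ndarray, depth: int) -> int:
        node = tree._new_node()
        tree.value[node] = float(y[idx].mean())
        if depth >= max_depth:
            return node
        split = _best_split(X[idx], y[idx], min_leaf)
        if split is None:
            return node
        j, thr = split
        mask = X[idx, j] <= thr
        left = grow(idx[mask], depth + 1)
        right = grow(idx[~mask], depth + 1)
        tree.feature[node] = j
        tree.threshold[node] = thr
        tree.left[node] = left
        tree.right[node] = right
        return node

    grow(np.arange(len(X)), 0)
    tree.finalize()
    return tree


if _HAVE_NUMBA:

    @numba.njit(cache=False, fastmath=False)
    def _predict_flat(X, feature, threshold, left, right, value, roots, initial, lr):  # pragma: no cover - jitted
        n = X.shape[0]
        nt = len(roots)
        out = np.empty(n)
        for i in range(n):
            acc = 0.0
            for t in range(nt):
                node = roots[t]
                f = feature[node]
                while f >= 0:
                    if X[i, f] <= threshold[node]:
                        node = left[node]
                    else:
                        node = right[node]
                    f = feature[node]
                acc += value[node]
            out[i] = initial + lr * acc
        return out


@dataclass
class GBDTEnsemble:
    """Fitted boosted ensemble. ``train_losses`` tracks the training MSE
    after each boosting iteration."""

    params: GBDTParams
    initial: float
    trees: list = field(default_factory=list)
    train_losses: list = field(default_factory=list)

    def _flattened(self):
        """Trees concatenated with node indices rebased to global positions
        (one dependent load fewer per hop in the jitted kernel)."""
        n_nodes = sum(len(t.feature) for t in self.trees)
        if getattr(self, "_flat", None) is None or self._flat[0].shape[0] != n_nodes:
            sizes = np.array([len(t.feature) for t in self.trees], dtype=np.int64)
            roots = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.int64)
            feature = np.concatenate([t.feature for t in self.trees]).astype(np.int64)
            threshold = np.concatenate([t.threshold for t in self.trees])
            base = np.repeat(roots, sizes)
            left = np.concatenate([t.left for t in self.trees]).astype(np.int64) + base
            right = np.concatenate([t.right for t in self.trees]).astype(np.int64) + base
            value = np.concatenate([t.value for t in self.trees])
            self._flat = (feature, threshold, left, right, value, roots)
        return self._flat

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
        if X.ndim == 1:
            X = X[None, :]
        if not self.trees:
            return np.full(len(X), self.initial, dtype=np.float64)
        if _HAVE_NUMBA:
            feature, threshold, left, right, value, roots = self._flattened()
            return _predict_flat(
                X, feature, threshold, left, right, value, roots, self.initial, self.params.learning_rate
            )
        out = np.full(len(X), self.initial, dtype=np.float64)
        lr = self.params.learning_rate
        for tree in self.trees:
            out += lr * tree.predict(X)
        return out

    # sklearn-style aliases so the ensemble drops into the model registry
    def fit(self, X: np.ndarray, y: np.ndarray) -> "GBDTEnsemble":  # pragma: no cover
        fitted = fit_gbdt(X, y, self.params)
        self.initial, self.trees, self.train_losses = fitted.initial, fitted.trees, fitted.train_losses
        return self


def fit_gbdt(X: np.ndarray, y: np.ndarray, params: GBDTParams | None = None) -> GBDTEnsemble:
    """Fit the least-squares boosting ensemble.

    A constant target yields an ensemble of zero trees predicting the mean
    (with a warning). Deterministic for a given seed.
    """
    params = params or GBDTParams()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one target per row")
    if not np.isfinite(y).all():
        raise ValueError("targets must be finite")
    if len(y) < 2 * params.min_samples_leaf:
        raise ValueError(
            f"need at least {2 * params.min_samples_leaf} records for min_samples_leaf={params.min_samples_leaf}"
        )

    ens = GBDTEnsemble(params=params, initial=float(y.mean()))
    if np.ptp(y) == 0:
        warnings.warn("constant target: ensemble predicts the mean with zero trees", stacklevel=2)
        ens.train_losses = [0.0]
        return ens

    rng = np.random.default_rng(params.seed)
    pred = np.full(len(y), ens.initial)
    n = len(y)
    for _ in range(params.n_trees):
        residual = y - pred
        if params.subsample < 1.0:
            take = rng.choice(n, size=max(2 * params.min_samples_leaf, int(round(params.subsample * n))), replace=False)
        else:
            take = np.arange(n)
        tree = _fit_tree(X[take], residual[take], params.max_depth, params.min_samples_leaf)
        ens.trees.append(tree)
        pred = pred + params.learning_rate * tree.predict(X)
        ens.train_losses.append(float(np.mean((y - pred) ** 2)))
    return ens
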