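"""Model-agnostic Shapley additive attributions.

Each prediction decomposes as

    f(x) = base_value + sum_j phi_j                               (efficiency)

where the base value is the mean model prediction over a background sample
and phi_j is the Shapley value of feature j under the interventional value
function: v(S) is the mean prediction over background rows with the features
in S replaced by their values at the explained point x. This is the
cooperative-game formulation — phi_j averages the marginal contribution of
feature j over all coalitions S, weighted |S|!(m-|S|-1)!/m!.

Two estimators are provided: exact coalition enumeration (2^m value
evaluations, limited to m <= 15 features) and a seeded permutation-sampling
estimator with per-feature standard errors for wider feature sets. A
brute-force m!-permutation oracle is exposed for testing; it must agree with
the exact estimator to numerical precision.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Attribution",
    "AttributionSet",
    "exact_shapley",
    "sampled_shapley",
    "brute_force_shapley",
    "summary_data",
    "decision_path",
    "explain_records",
]

EXACT_FEATURE_LIMIT = 15


@dataclass
class Attribution:
    """Additive explanation of one prediction: base_value + sum(phi) =
    prediction."""

    base_value: float
    phi: np.ndarray
    prediction: float
    feature_names: list = field(default_factory=list)
    standard_errors: np.ndarray | None = None

    @property
    def closure_gap(self) -> float:
        return float(self.prediction - self.base_value - self.phi.sum())


@dataclass
class AttributionSet:
    attributions: list
    feature_names: list
    feature_values: np.ndarray  # (n_records, m) values at the explained points

    def phi_matrix(self) -> np.ndarray:
        return np.vstack([a.phi for a in self.attributions])

    def to_frame(self) -> pd.DataFrame:
        """Record x feature phi table plus base value and prediction."""
        phi = self.phi_matrix()
        df = pd.DataFrame(phi, columns=[f"phi_{n}" for n in self.feature_names])
        df.insert(0, "base_value", [a.base_value for a in self.attributions])
        df["prediction"] = [a.prediction for a in self.attributions]
        return df


def _as_2d(background: np.ndarray) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.ndim != 2 or len(bg) == 0:
        raise ValueError("background must be a non-empty 2-D sample")
    return bg


def _coalition_values(predict_fn, background: np.ndarray, x: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """v(S) for every bitmask in ``masks``: mean prediction over background
    rows with the features in S taken from x."""
    B, m = background.shape
    values = np.empty(len(masks), dtype=float)
    chunk = max(1, int(2_000_000 // max(B, 1)))
    bits = (masks[:, None] >> np.arange(m)[None, :]) & 1  # (n_masks, m)
    for start in range(0, len(masks), chunk):
        sel = bits[start : start + chunk].astype(bool)
        n = len(sel)
        rows = np.broadcast_to(background, (n, B, m)).copy()
        rows[np.broadcast_to(sel[:, None, :], (n, B, m))] = np.broadcast_to(
            x[None, None, :], (n, B, m)
        )[np.broadcast_to(sel[:, None, :], (n, B, m))]
        preds = np.asarray(predict_fn(rows.reshape(n * B, m)), dtype=float)
        values[start : start + n] = preds.reshape(n, B).mean(axis=1)
    return values


def exact_shapley(
    predict_fn,
    background: np.ndarray,
    x: np.ndarray,
    feature_names: list | None = None,
) -> Attribution:
    """Exact Shapley attribution by coalition enumeration.

    Evaluates all 2^m interventional coalition values; refuses more than
    ``EXACT_FEATURE_LIMIT`` features (use :func:`sampled_shapley` instead).
    Efficiency holds to numerical precision: the phi sum telescopes from
    v(empty) (the base value) to v(full) = f(x).
    """
    background = _as_2d(background)
    x = np.asarray(x, dtype=float).ravel()
    m = background.shape[1]
    if x.shape[0] != m:
        raise ValueError("x and background disagree on feature count")
    if m > EXACT_FEATURE_LIMIT:
        raise ValueError(
            f"{m} features exceeds the exact-mode limit {EXACT_FEATURE_LIMIT}; use sampled_shapley"
        )

    masks = np.arange(2**m, dtype=np.int64)
    v = _coalition_values(predict_fn, background, x, masks)

    fact = [math.factorial(i) for i in range(m + 1)]
    w = np.array([fact[s] * fact[m - s - 1] / fact[m] for s in range(m)])
    popcount = np.array([bin(int(mask)).count("1") for mask in masks])

    phi = np.zeros(m)
    for j in range(m):
        bit = 1 << j
        without = masks[(masks & bit) == 0]
        sizes = popcount[without]
        phi[j] = float(np.sum(w[sizes] * (v[without | bit] - v[without])))

    return Attribution(
        base_value=float(v[0]),
        phi=phi,
        prediction=float(v[-1]),
        feature_names=list(feature_names) if feature_names else [f"f{j}" for j in range(m)],
    )


def brute_force_shapley(predict_fn, background: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Oracle: average marginal contributions over all m! feature orderings.

    Exponential in m (test use only, m <= ~7). Mathematically identical to
    :func:`exact_shapley`; kept as an independent cross-check because it
    never touches the coalition-weight formula.
    """
    background = _as_2d(background)
    x = np.asarray(x, dtype=float).ravel()
    m = background.shape[1]
    masks = np.arange(2**m, dtype=np.int64)
    v = _coalition_values(predict_fn, background, x, masks)
    phi = np.zeros(m)
    n_perm = 0
    for order in itertools.permutations(range(m)):
        mask = 0
        for j in order:
            new = mask | (1 << j)
            phi[j] += v[new] - v[mask]
            mask = new
        n_perm += 1
    return phi / n_perm


def sampled_shapley(
    predict_fn,
    background: np.ndarray,
    x: np.ndarray,
    n_permutations: int = 2000,
    seed: int = 0,
    feature_names: list | None = None,
) -> Attribution:
    """Permutation-sampling Shapley estimator with standard errors.

    Unbiased for the exact values; deterministic per seed. After averaging,
    the small Monte-Carlo closure residual (prediction - base - sum phi) is
    distributed over features proportionally to |phi| so the efficiency
    identity holds exactly on the reported attribution.
    """
    background = _as_2d(background)
    x = np.asarray(x, dtype=float).ravel()
    m = background.shape[1]
    if n_permutations < 2:
        raise ValueError("need n_permutations >= 2")
    rng = np.random.default_rng(seed)
    B = len(background)

    base = float(np.mean(np.asarray(predict_fn(background), dtype=float)))
    fx_rows = np.broadcast_to(x, (B, m))
    prediction = float(np.mean(np.asarray(predict_fn(fx_rows), dtype=float)))

    contrib = np.zeros((n_permutations, m))
    # batch permutations to keep predict calls large and few
    batch = max(1, int(200_000 // max(B * (m + 1), 1)))
    p = 0
    while p < n_permutations:
        nb = min(batch, n_permutations - p)
        orders = np.vstack([rng.permutation(m) for _ in range(nb)])
        # rows: for each permutation, m+1 coalition states x B background rows
        states = np.empty((nb, m + 1, B, m))
        for b in range(nb):
            row = background.copy()
            states[b, 0] = row
            for step, j in enumerate(orders[b], start=1):
                row = row.copy()
                row[:, j] = x[j]
                states[b, step] = row
        preds = np.asarray(predict_fn(states.reshape(nb * (m + 1) * B, m)), dtype=float)
        v = preds.reshape(nb, m + 1, B).mean(axis=2)
        deltas = np.diff(v, axis=1)  # (nb, m) marginal contributions in order
        for b in range(nb):
            contrib[p + b, orders[b]] = deltas[b]
        p += nb

    phi = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / np.sqrt(n_permutations)

    gap = prediction - base - float(phi.sum())
    denom = float(np.abs(phi).sum())
    if denom > 0:
        phi = phi + gap * np.abs(phi) / denom
    # else: all-zero phi, leave the (tiny) gap in place

    return Attribution(
        base_value=base,
        phi=phi,
        prediction=prediction,
        feature_names=list(feature_names) if feature_names else [f"f{j}" for j in range(m)],
        standard_errors=se,
    )


def explain_records(
    predict_fn,
    background: np.ndarray,
    X: np.ndarray,
    feature_names: list | None = None,
    mode: str = "auto",
    n_permutations: int = 2000,
    seed: int = 0,
) -> AttributionSet:
    """Attribute every row of ``X``; exact when the feature count allows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = X.shape[1]
    if mode not in ("auto", "exact", "sampled"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and m <= EXACT_FEATURE_LIMIT)
    names = list(feature_names) if feature_names else [f"f{j}" for j in range(m)]
    atts = []
    for i, x in enumerate(X):
        if use_exact:
            atts.append(exact_shapley(predict_fn, background, x, names))
        else:
            atts.append(sampled_shapley(predict_fn, background, x, n_permutations, seed + i, names))
    return AttributionSet(atts, names, X.copy())


def summary_data(attribution_set: AttributionSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Global importance ranking and the beeswarm/bar point cloud.

    Returns (ranking, points): ``ranking`` orders features by mean |phi|
    descending (ties broken alphabetically); ``points`` holds one (feature,
    feature value, phi) row per record and feature, the data behind summary
    and bar plots.
    """
    if not attribution_set.attributions:
        raise ValueError("empty attribution set")
    phi = attribution_set.phi_matrix()
    names = attribution_set.feature_names
    mean_abs = np.abs(phi).mean(axis=0)
    order = sorted(range(len(names)), key=lambda j: (-mean_abs[j], names[j]))
    ranking = pd.DataFrame(
        {
            "feature": [names[j] for j in order],
            "mean_abs_phi": [float(mean_abs[j]) for j in order],
            "mean_phi": [float(phi[:, j].mean()) for j in order],
            "rank": np.arange(1, len(names) + 1),
        }
    )
    rows = []
    for i in range(phi.shape[0]):
        for j, name in enumerate(names):
            rows.append(
                {
                    "record": i,
                    "feature": name,
                    "value": float(attribution_set.feature_values[i, j]),
                    "phi": float(phi[i, j]),
                }
            )
    return ranking, pd.DataFrame(rows)


def decision_path(attribution: Attribution, feature_order: list) -> pd.DataFrame:
    """Cumulative attribution walk from base value to prediction.

    ``feature_order`` must be a permutation of the attribution's features;
    step j adds phi of feature_order[j]. The data behind decision plots.
    """
    names = attribution.feature_names
    if sorted(feature_order) != sorted(names):
        raise ValueError("feature_order must be a permutation of the attribution's features")
    idx = {n: j for j, n in enumerate(names)}
    cum = [attribution.base_value]
    for name in feature_order:
        cum.append(cum[-1] + float(attribution.phi[idx[name]]))
    return pd.DataFrame(
        {"step": range(len(cum)), "feature": ["base"] + list(feature_order), "cumulative": cum}
    )
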