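"""Regression benchmark: metrics, model registry and the two-scenario harness.

Models are compared on the published metric set — RMSLE (root mean squared
logarithmic error, robust to large-interval outliers), R² and MAE on a
held-out worker-disjoint test set, plus the mean ± sd of R² over
worker-disjoint cross-validation folds. Result tables use the standard
column layout: Model, RMSLE, R2, MAE, CV-R2 (mean ± sd).

The registry maps model names to zero-argument factories returning anything
with ``fit(X, y)`` / ``predict(X)``. The built-in boosted-tree learner is
always available; scikit-learn comparators (decision tree, random forest,
gradient boosting) and, when importable, xgboost/lightgbm are optional
adapters. A failing adapter is recorded as a failed row and the bench
continues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bodyparts import PART_NAMES
from .features import FEATURE_COLUMNS, FeatureTable, SplitPlan
from .gbdt import GBDTParams, fit_gbdt

__all__ = [
    "EvalResult",
    "regression_metrics",
    "default_registry",
    "evaluate_models",
    "evaluate_severity_models",
    "learning_curve",
    "results_to_frame",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = ("Model", "RMSLE", "R2", "MAE", "CV-R2 (mean ± sd)")


# --------------------------------------------------------------------------
# metrics


def regression_metrics(y_true, y_pred) -> tuple[float, float, float]:
    """(RMSLE, R², MAE).

    RMSLE = sqrt(mean((log1p(y_pred) - log1p(y_true))²)); negative
    predictions are clipped to 0 with a warning (log1p would be undefined).
    R² is 1 - SS_res/SS_tot and is NaN (with a warning) for a constant
    y_true. Requires non-negative y_true and equal non-zero lengths.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be non-empty and of equal length")
    if (y_true < 0).any():
        raise ValueError("RMSLE requires non-negative true values")
    if (y_pred < 0).any():
        warnings.warn("negative predictions clipped to 0 for RMSLE", stacklevel=2)
    clipped = np.clip(y_pred, 0.0, None)
    rmsle = float(np.sqrt(np.mean((np.log1p(clipped) - np.log1p(y_true)) ** 2)))
    mae = float(np.mean(np.abs(y_true - y_pred)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("constant y_true: R² undefined, reported as NaN", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot
    return rmsle, r2, mae


# --------------------------------------------------------------------------
# model registry


class _BuiltinGBDT:
    def __init__(self, params: GBDTParams | None = None):
        self.params = params or GBDTParams()
        self._ens = None

    def fit(self, X, y):
        self._ens = fit_gbdt(X, y, self.params)
        return self

    def predict(self, X):
        return self._ens.predict(np.asarray(X, dtype=float))


def default_registry(seed: int = 0, include_optional: bool = True) -> dict:
    """Name -> factory map. The built-in learner needs no third-party
    booster; classic comparators come from scikit-learn, and the gradient
    boosting libraries xgboost/lightgbm join when importable."""
    from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
    from sklearn.tree import DecisionTreeRegressor

    registry: dict = {
        "gbdt_builtin": lambda: _BuiltinGBDT(GBDTParams(seed=seed)),
        "decision_tree": lambda: DecisionTreeRegressor(max_depth=6, min_samples_leaf=5, random_state=seed),
        "random_forest": lambda: RandomForestRegressor(
            n_estimators=200, min_samples_leaf=3, random_state=seed, n_jobs=1
        ),
        "gradient_boosting": lambda: GradientBoostingRegressor(
            n_estimators=300, max_depth=3, learning_rate=0.05, random_state=seed
        ),
    }
    if include_optional:
        try:
            import xgboost as xgb

            registry["xgboost"] = lambda: xgb.XGBRegressor(
                n_estimators=300, max_depth=3, learning_rate=0.05, random_state=seed, n_jobs=1,
                verbosity=0,
            )
        except ImportError:  # pragma: no cover
            pass
        try:
            import lightgbm as lgb

            registry["lightgbm"] = lambda: lgb.LGBMRegressor(
                n_estimators=300, max_depth=3, learning_rate=0.05, random_state=seed, n_jobs=1,
                verbose=-1,
            )
        except ImportError:  # pragma: no cover
            pass
    return registry


@dataclass
class EvalResult:
    model: str
    rmsle: float
    r2: float
    mae: float
    cv_r2_mean: float
    cv_r2_sd: float
    failed: bool = False
    error: str = ""
    part: str = ""  # set in the per-part severity scenario


def results_to_frame(results: list[EvalResult]) -> pd.DataFrame:
    """Delimited result table in the standard benchmark column layout."""
    rows = []
    for r in results:
        cv = "failed" if r.failed else f"{r.cv_r2_mean:.3f} ± {r.cv_r2_sd:.3f}"
        rows.append(
            {
                "Model": r.model,
                "RMSLE": np.nan if r.failed else round(r.rmsle, 4),
                "R2": np.nan if r.failed else round(r.r2, 4),
                "MAE": np.nan if r.failed else round(r.mae, 4),
                "CV-R2 (mean ± sd)": cv,
            }
        )
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


# --------------------------------------------------------------------------
# harness


def _fit_eval(factory, X_tr, y_tr, X_te, y_te) -> tuple[float, float, float]:
    model = factory()
    model.fit(X_tr, y_tr)
    pred = np.asarray(model.predict(X_te), dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return regression_metrics(y_te, pred)


def _cv_r2(factory, X, y, folds_local: list[list[int]]) -> tuple[float, float]:
    scores = []
    for f, hold in enumerate(folds_local):
        hold = np.asarray(hold, dtype=int)
        mask = np.ones(len(X), dtype=bool)
        mask[hold] = False
        model = factory()
        model.fit(X[mask], y[mask])
        pred = np.asarray(model.predict(X[hold]), dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, r2, _ = regression_metrics(np.clip(y[hold], 0, None), pred)
        scores.append(r2)
    arr = np.asarray(scores, dtype=float)
    return float(np.nanmean(arr)), float(np.nanstd(arr, ddof=1)) if len(arr) > 1 else 0.0


def _folds_local(plan: SplitPlan) -> list[list[int]]:
    """Fold record indices re-expressed as positions within the train set."""
    pos = {int(g): i for i, g in enumerate(plan.train_index)}
    return [[pos[int(i)] for i in fold] for fold in plan.folds]


def evaluate_models(
    registry: dict,
    table: FeatureTable,
    plan: SplitPlan,
    scenario: str = "interval",
) -> list[EvalResult]:
    """Fit every registry model and evaluate the requested scenario.

    ``interval``: target is weeks to the next appointment. ``severity``:
    one model per body part (see :func:`evaluate_severity_models`); this
    entry point then returns the flat list over all parts.
    """
    if not registry:
        raise ValueError("empty model registry")
    if scenario == "severity":
        per_part = evaluate_severity_models(registry, table, plan)
        return [r for results in per_part.values() for r in results]
    if scenario != "interval":
        raise ValueError(f"unknown scenario {scenario!r}")

    X = table.X
    y = table.y_interval()
    tr = np.asarray(plan.train_index, dtype=int)
    te = np.asarray(plan.test_index, dtype=int)
    folds_local = _folds_local(plan)

    results = []
    for name, factory in registry.items():
        try:
            rmsle, r2, mae = _fit_eval(factory, X[tr], y[tr], X[te], y[te])
            cv_mean, cv_sd = _cv_r2(factory, X[tr], y[tr], folds_local) if folds_local else (float("nan"), float("nan"))
            results.append(EvalResult(name, rmsle, r2, mae, cv_mean, cv_sd))
        except Exception as exc:  # adapter failure: record and continue
            results.append(EvalResult(name, np.nan, np.nan, np.nan, np.nan, np.nan, failed=True, error=str(exc)))
    return results


def evaluate_severity_models(
    registry: dict,
    table: FeatureTable,
    plan: SplitPlan,
    parts: tuple[str, ...] = PART_NAMES,
    min_records: int = 30,
) -> dict[str, list[EvalResult]]:
    """Per-body-part next-severity benchmark: one result table per part.

    Each part's model trains only on records where that part is currently
    scored (> 0) — parts a worker never had restricted carry no signal for
    their next severity. Parts with fewer than ``min_records`` such training
    records are reported as failed rows rather than fitted on noise.
    """
    X = table.X
    tr = np.asarray(plan.train_index, dtype=int)
    te = np.asarray(plan.test_index, dtype=int)
    part_col = {p: i for i, p in enumerate(FEATURE_COLUMNS)}
    out: dict[str, list[EvalResult]] = {}
    for part in parts:
        y = table.y_next_score(part)
        has_history_tr = tr[X[tr, part_col[part]] > 0]
        has_history_te = te[X[te, part_col[part]] > 0]
        results = []
        for name, factory in registry.items():
            if len(has_history_tr) < min_records or len(has_history_te) < 5:
                results.append(
                    EvalResult(name, np.nan, np.nan, np.nan, np.nan, np.nan, failed=True,
                               error="insufficient part history", part=part)
                )
                continue
            try:
                rmsle, r2, mae = _fit_eval(
                    factory, X[has_history_tr], y[has_history_tr], X[has_history_te], y[has_history_te]
                )
                results.append(EvalResult(name, rmsle, r2, mae, float("nan"), float("nan"), part=part))
            except Exception as exc:
                results.append(EvalResult(name, np.nan, np.nan, np.nan, np.nan, np.nan,
                                          failed=True, error=str(exc), part=part))
        out[part] = results
    return out


def learning_curve(
    factory,
    X: np.ndarray,
    y: np.ndarray,
    workers: np.ndarray,
    train_sizes: list[int],
    seed: int = 0,
    val_fraction: float = 0.2,
    val_index: np.ndarray | None = None,
) -> list[tuple[int, float, float]]:
    """(size, train R², validation R²) over growing nested training sets.

    A worker-disjoint validation set is fixed once (or supplied explicitly
    via ``val_index``, e.g. the benchmark's test set); training subsets are
    nested prefixes of a seeded shuffle so the curve reflects sample size,
    not resampling luck. Duplicate sizes are dropped with a warning; sizes
    smaller than 10 records are skipped with a warning.
    """
    sizes = sorted(set(int(s) for s in train_sizes))
    if len(sizes) != len(train_sizes):
        warnings.warn("duplicate train sizes deduplicated", stacklevel=2)

    rng = np.random.default_rng(seed)
    if val_index is not None:
        is_val = np.zeros(len(X), dtype=bool)
        is_val[np.asarray(val_index, dtype=int)] = True
    else:
        uniq = rng.permutation(np.unique(workers))
        n_val_workers = max(1, int(round(val_fraction * len(uniq))))
        val_workers = set(uniq[:n_val_workers])
        is_val = np.isin(workers, sorted(val_workers))
    X_val, y_val = X[is_val], y[is_val]
    pool = np.where(~is_val)[0]
    pool = pool[rng.permutation(len(pool))]

    points = []
    for size in sizes:
        if size < 10:
            warnings.warn(f"train size {size} too small, skipped", stacklevel=2)
            continue
        if size > len(pool):
            warnings.warn(f"train size {size} exceeds available {len(pool)} records, skipped", stacklevel=2)
            continue
        take = np.sort(pool[:size])
        model = factory()
        model.fit(X[take], y[take])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, r2_tr, _ = regression_metrics(y[take], np.asarray(model.predict(X[take]), dtype=float))
            _, r2_val, _ = regression_metrics(y_val, np.asarray(model.predict(X_val), dtype=float))
        points.append((size, r2_tr, r2_val))
    return points
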