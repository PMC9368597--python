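"""Evaluation metrics and the two-scenario model bench."""

import numpy as np
import pytest

from ohpp.bench import (
    RESULT_COLUMNS,
    default_registry,
    evaluate_models,
    evaluate_severity_models,
    learning_curve,
    regression_metrics,
    results_to_frame,
)
from ohpp.bodyparts import PART_NAMES
from ohpp.gbdt import GBDTParams


def _builtin_factory(seed=0, n_trees=150):
    from ohpp.bench import _BuiltinGBDT

    return lambda: _BuiltinGBDT(GBDTParams(n_trees=n_trees, seed=seed))


class TestMetrics:
    def test_perfect_prediction(self, rng):
        y = rng.uniform(1, 50, size=20)
        assert regression_metrics(y, y) == pytest.approx((0.0, 1.0, 0.0))

    def test_rmsle_unit_case(self):
        rmsle, _, _ = regression_metrics([np.e - 1], [0.0])
        assert rmsle == pytest.approx(1.0)

    def test_negative_predictions_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            rmsle, _, _ = regression_metrics([0.0, 1.0], [-5.0, 1.0])
        assert rmsle == pytest.approx(0.0, abs=1e-12)

    def test_constant_truth_r2_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            _, r2, _ = regression_metrics([2.0, 2.0], [1.0, 3.0])
        assert np.isnan(r2)

    def test_empty_and_mismatched_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([], [])
        with pytest.raises(ValueError):
            regression_metrics([1.0], [1.0, 2.0])

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import mean_absolute_error, mean_squared_log_error, r2_score

        y = rng.uniform(0, 60, size=50)
        p = y + rng.normal(scale=5, size=50)
        p = np.clip(p, 0, None)
        rmsle, r2, mae = regression_metrics(y, p)
        assert rmsle == pytest.approx(np.sqrt(mean_squared_log_error(y, p)))
        assert r2 == pytest.approx(r2_score(y, p))
        assert mae == pytest.approx(mean_absolute_error(y, p))

    def test_rmsle_dampens_outliers_relative_to_rmse(self):
        """Appending one 100x outlier inflates RMSLE by a smaller factor than
        raw-scale RMSE — the log scale absorbs magnitude."""
        y = np.array([10.0, 12, 9, 11, 10, 13, 8, 12, 11, 10])
        p = y + 1.0
        rmsle0, _, _ = regression_metrics(y, p)
        rmse0 = np.sqrt(np.mean((y - p) ** 2))
        y1 = np.append(y, 10.0)
        p1 = np.append(p, 1000.0)
        rmsle1, _, _ = regression_metrics(y1, p1)
        rmse1 = np.sqrt(np.mean((y1 - p1) ** 2))
        assert rmsle1 / rmsle0 < rmse1 / rmse0


class TestBench:
    def test_single_model_registry_single_row(self, feature_table, split_plan):
        results = evaluate_models({"gbdt_builtin": _builtin_factory()}, feature_table, split_plan)
        assert len(results) == 1 and results[0].model == "gbdt_builtin"
        assert results[0].rmsle >= 0 and results[0].r2 <= 1

    def test_empty_registry_rejected(self, feature_table, split_plan):
        with pytest.raises(ValueError, match="registry"):
            evaluate_models({}, feature_table, split_plan)

    def test_failing_adapter_recorded_not_raised(self, feature_table, split_plan):
        class Broken:
            def fit(self, X, y):
                raise RuntimeError("boom")

        results = evaluate_models(
            {"broken": Broken, "gbdt_builtin": _builtin_factory()}, feature_table, split_plan
        )
        by_name = {r.model: r for r in results}
        assert by_name["broken"].failed and "boom" in by_name["broken"].error
        assert not by_name["gbdt_builtin"].failed

    def test_severity_scenario_one_table_per_part(self, feature_table, split_plan):
        per_part = evaluate_severity_models(
            {"gbdt_builtin": _builtin_factory(n_trees=50)}, feature_table, split_plan
        )
        assert set(per_part) == set(PART_NAMES)
        for results in per_part.values():
            assert len(results) == 1

    def test_builtin_beats_single_tree_on_planted_cohort(self, feature_table, split_plan):
        """Boosting many shallow trees outperforms one regression tree in
        worker-disjoint CV on the planted-interval cohort."""
        from sklearn.tree import DecisionTreeRegressor

        registry = {
            "gbdt_builtin": _builtin_factory(),
            "decision_tree": lambda: DecisionTreeRegressor(max_depth=6, min_samples_leaf=5, random_state=0),
        }
        results = {r.model: r for r in evaluate_models(registry, feature_table, split_plan)}
        assert results["gbdt_builtin"].cv_r2_mean >= results["decision_tree"].cv_r2_mean

    def test_result_table_layout(self, feature_table, split_plan):
        results = evaluate_models({"gbdt_builtin": _builtin_factory(n_trees=30)}, feature_table, split_plan)
        frame = results_to_frame(results)
        assert tuple(frame.columns) == RESULT_COLUMNS

    def test_default_registry_has_builtin(self):
        registry = default_registry(include_optional=False)
        assert "gbdt_builtin" in registry and "decision_tree" in registry


class TestLearningCurve:
    def test_full_size_matches_bench_value(self, feature_table, split_plan):
        factory = _builtin_factory()
        results = evaluate_models({"m": factory}, feature_table, split_plan)
        pts = learning_curve(
            factory,
            feature_table.X,
            feature_table.y_interval(),
            feature_table.workers,
            [len(split_plan.train_index)],
            seed=0,
            val_index=np.asarray(split_plan.test_index),
        )
        assert len(pts) == 1
        assert pts[0][2] == pytest.approx(results[0].r2, abs=1e-9)

    def test_validation_score_improves_with_data(self, feature_table):
        pts = learning_curve(
            _builtin_factory(),
            feature_table.X,
            feature_table.y_interval(),
            feature_table.workers,
            [40, 120, 250],
            seed=1,
        )
        sizes = [p[0] for p in pts]
        vals = [p[2] for p in pts]
        assert sizes == sorted(sizes)
        assert vals[-1] > vals[0]

    def test_duplicate_sizes_deduplicated_with_warning(self, feature_table):
        with pytest.warns(UserWarning, match="duplicate"):
            pts = learning_curve(
                _builtin_factory(n_trees=20),
                feature_table.X,
                feature_table.y_interval(),
                feature_table.workers,
                [60, 60],
                seed=1,
            )
        assert len(pts) == 1

    def test_tiny_sizes_skipped_with_warning(self, feature_table):
        with pytest.warns(UserWarning, match="too small"):
            pts = learning_curve(
                _builtin_factory(n_trees=20),
                feature_table.X,
                feature_table.y_interval(),
                feature_table.workers,
                [2, 80],
                seed=1,
            )
        assert [p[0] for p in pts] == [80]
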