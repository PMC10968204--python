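import numpy as np
import pandas as pd
import pytest

from microeda.models import (
    REVERSE_TARGETS,
    EvalResult,
    ModelSpec,
    evaluate,
    make_estimator,
    model_grid,
    rank_models,
    reverse_models,
    shapley_summary,
)
from microeda.shapley import linear_shapley, shapley_values

RF_SMALL = {"n_estimators": 100}
ENV4 = ["Temperature", "CO2", "Humid", "IR"]


class TestEvaluate:
    def test_rf_learns_deterministic_signal(self, learnable_table):
        spec = ModelSpec("random_forest", RF_SMALL, seed=0)
        res = evaluate(learnable_table, "SCL", ENV4, spec, "split_70_30")
        assert res.mean_r2 > 0.9
        assert res.mean_r2 == pytest.approx(np.mean(res.fold_r2))

    def test_noise_target_has_no_skill(self, learnable_table):
        scores = []
        for seed in range(10):
            spec = ModelSpec("random_forest", RF_SMALL, seed=seed)
            res = evaluate(learnable_table, "shuffled", ENV4, spec,
                           "split_70_30", n_repeats=1)
            scores.append(res.mean_r2)
        assert np.mean(scores) <= 0.1

    def test_loso_fold_count_and_isolation(self, learnable_table):
        # target carries a large subject-specific offset: a model that saw
        # the held-out subject would score ~1, a properly isolated one
        # cannot predict the unseen offset
        df = learnable_table.copy()
        offsets = {f"S{i}": 10.0 * i for i in range(5)}
        df["y"] = df["subject"].map(offsets) + 0.01 * df["Temperature"]
        res = evaluate(df, "y", ENV4, ModelSpec("random_forest", RF_SMALL),
                       "loso")
        assert len(res.fold_r2) == 5
        assert res.mean_r2 < 0.5

    def test_single_subject_loso_rejected(self, learnable_table):
        df = learnable_table.assign(subject="S0")
        with pytest.raises(ValueError):
            evaluate(df, "SCL", ENV4, ModelSpec("linear"), "loso")

    def test_constant_target_rejected(self, learnable_table):
        df = learnable_table.assign(const=1.0)
        with pytest.raises(ValueError):
            evaluate(df, "const", ENV4, ModelSpec("linear"))

    def test_reproducible_given_seed(self, learnable_table):
        spec = ModelSpec("random_forest", RF_SMALL, seed=3)
        a = evaluate(learnable_table, "SCL", ENV4, spec, "split_70_30")
        b = evaluate(learnable_table, "SCL", ENV4, spec, "split_70_30")
        assert a.fold_r2 == b.fold_r2


class TestRanking:
    def _res(self, family, r2):
        return EvalResult(target="t", family=family, scheme="loso",
                          mean_r2=r2, fold_r2=[r2])

    def test_descending_order(self):
        out = rank_models([self._res("linear", 0.1),
                           self._res("random_forest", 0.8),
                           self._res("support_vector", 0.4)])
        assert out == ["random_forest", "support_vector", "linear"]

    def test_ties_alphabetical(self):
        out = rank_models([self._res("support_vector", 0.5),
                           self._res("linear", 0.5)])
        assert out == ["linear", "support_vector"]

    def test_single_result(self):
        assert rank_models([self._res("linear", 0.0)]) == ["linear"]


class TestShapley:
    def test_linear_closed_form_ordering_and_accuracy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, size=(200, 2))  # unit-scale features
        y = 3.0 * X[:, 0] + 1.0 * X[:, 1]
        df = pd.DataFrame(X, columns=["x1", "x2"])
        df["y"] = y
        df["subject"] = "S0"
        res = evaluate(df, "y", ["x1", "x2"], ModelSpec("linear"))
        attr = shapley_summary(res, df, seed=0)
        assert attr.ordering == ["x1", "x2"]
        preds = res.model.predict(df[["x1", "x2"]].to_numpy())
        exact = linear_shapley(res.model.coef_, res.model.intercept_,
                               df[["x1", "x2"]].to_numpy()[:20],
                               df[["x1", "x2"]].to_numpy())
        np.testing.assert_allclose(exact.values.sum(axis=1) + exact.baseline,
                                   preds[:20], atol=1e-10)

    def test_exact_local_accuracy_for_forest(self, learnable_table):
        spec = ModelSpec("random_forest", {"n_estimators": 50}, seed=0)
        res = evaluate(learnable_table, "SCL", ENV4, spec)
        attr = shapley_summary(res, learnable_table, seed=1,
                               max_instances=15, background_size=8)
        assert attr.method == "exact"
        # recompute with the same subsampling to check the identity
        rng = np.random.default_rng(1)
        X_all = learnable_table[ENV4].to_numpy()
        bg = X_all[rng.choice(len(X_all), 8, replace=False)]
        inst = X_all[rng.choice(len(X_all), 15, replace=False)]
        preds = res.model.predict(inst)
        np.testing.assert_allclose(attr.values.sum(axis=1) + attr.baseline,
                                   preds, atol=1e-6)

    def test_permutation_local_accuracy(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        bg = rng.normal(size=(10, 3))

        def predict(A):
            return np.sin(A[:, 0]) + A[:, 1] * A[:, 2]

        attr = shapley_values(predict, X, bg, seed=0, method="permutation",
                              n_permutations=16)
        np.testing.assert_allclose(attr.values.sum(axis=1) + attr.baseline,
                                   predict(X), atol=1e-10)

    def test_null_feature_gets_no_attribution(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(100, 3))

        def predict(A):
            return 2.0 * A[:, 0]

        attr = shapley_values(predict, X, X[:20], seed=0, method="exact")
        assert attr.mean_abs.iloc[0] > 0.5
        assert np.abs(attr.values[:, 1]).mean() < 1e-10
        assert np.abs(attr.values[:, 2]).mean() < 1e-10

    def test_unfitted_model_rejected(self, learnable_table):
        res = EvalResult(target="SCL", family="linear", scheme="loso",
                         mean_r2=0.0, fold_r2=[], model=None,
                         feature_names=ENV4)
        with pytest.raises(ValueError):
            shapley_summary(res, learnable_table)


class TestDirections:
    def test_grid_shape(self, learnable_table):
        grid = model_grid(learnable_table, ["SCL", "NSSCR"], ENV4,
                          rf_params={"n_estimators": 30}, n_repeats=2)
        assert grid.shape == (6, 2)
        assert "loso-random_forest" in grid.index

    def test_reverse_models_cover_environment_targets(self, learnable_table):
        spec = ModelSpec("random_forest", {"n_estimators": 50}, seed=0)
        out = reverse_models(learnable_table, spec=spec, n_repeats=2,
                             max_instances=10)
        assert set(out) == set(REVERSE_TARGETS)
        # temperature is deterministically encoded in SCL and NSSCR
        assert out["Temperature"]["eval"].mean_r2 > 0.9
        top = out["Temperature"]["attribution"].ordering[0]
        assert top in ("SCL", "NSSCR")

    def test_estimator_families(self):
        assert make_estimator(ModelSpec("linear")).__class__.__name__ == \
            "LinearRegression"
        with pytest.raises(ValueError):
            ModelSpec("boosted_trees")
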