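"""Regressors, metrics, cross-validation, tuning and the stacking ensemble."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.ensemble import StackingRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from cacoperm import (
    CVConfig,
    ModelSpec,
    StackingEnsemble,
    cross_validate,
    evaluate,
    train_ensemble,
    train_model,
    tune_model,
)


def linear_data(rng, n=60, p=4, noise=0.0):
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"x{i}" for i in range(p)])
    beta = np.arange(1, p + 1, dtype=float)
    y = X.to_numpy() @ beta + noise * rng.standard_normal(n)
    return X, y


class TestTrainPredict:
    def test_mlr_interpolates_noiseless_linear_data(self, rng):
        X, y = linear_data(rng)
        m = train_model(ModelSpec("mlr"), X, y)
        assert evaluate(y, m.predict(X)).rmse < 1e-8

    def test_svm_defaults_are_reference_values(self):
        hp = ModelSpec("svm_rbf").resolved_hyperparams()
        assert hp == {"sigma": 0.015, "C": 2.0, "epsilon": 0.1}

    def test_mtry_exceeding_features_rejected(self, rng):
        X, y = linear_data(rng, p=10)
        with pytest.raises(ValueError, match="mtry"):
            train_model(ModelSpec("rf", {"mtry": 18, "n_trees": 10}), X, y)

    def test_column_permutation_invariance(self, rng):
        X, y = linear_data(rng, noise=0.1)
        m = train_model(ModelSpec("gbm", {"n_trees": 20}, seed=0), X, y)
        shuffled = X[list(X.columns[::-1])]
        assert np.array_equal(m.predict(X), m.predict(shuffled))

    def test_missing_column_rejected(self, rng):
        X, y = linear_data(rng)
        m = train_model(ModelSpec("mlr"), X, y)
        with pytest.raises(KeyError):
            m.predict(X.drop(columns=["x0"]))

    @pytest.mark.parametrize("kind", ["mlr", "pls", "svm_rbf", "rf", "gbm"])
    def test_each_kind_fits_and_predicts(self, rng, kind):
        X, y = linear_data(rng, n=80, p=6, noise=0.2)
        hp = {"rf": {"mtry": 2, "n_trees": 20}, "gbm": {"n_trees": 20}, "pls": {"ncomp": 3}}.get(kind, {})
        m = train_model(ModelSpec(kind, hp, seed=1), X, y)
        pred = m.predict(X)
        assert pred.shape == (80,) and np.isfinite(pred).all()


class TestEvaluate:
    def test_perfect_prediction(self):
        m = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.rmse == 0.0 and m.r2 == pytest.approx(1.0)

    def test_constant_prediction_r2_undefined(self):
        with pytest.warns(UserWarning):
            m = evaluate([0.0, 0.0], [1.0, 1.0])
        assert m.rmse == pytest.approx(1.0)
        assert m.r2 is None and m.r2_undefined

    def test_worked_example(self):
        m = evaluate([1.0, 2.0, 3.0], [1.1, 1.9, 3.2])
        assert m.rmse == pytest.approx(np.sqrt(0.06 / 3), abs=1e-12)
        # squared Pearson correlation, recomputed by hand: r = 2.1 /
        # sqrt(2 * 2.24667) = 0.99068, r^2 = 0.98145
        assert m.r2 == pytest.approx(0.98145, abs=5e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_arithmetic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 21))
        y, y_hat = rng.normal(size=n), rng.normal(size=n)
        m = evaluate(y, y_hat)
        rmse = np.sqrt(sum((a - b) ** 2 for a, b in zip(y, y_hat)) / n)
        sy, syh = y - y.mean(), y_hat - y_hat.mean()
        r = (sy * syh).sum() / np.sqrt((sy**2).sum() * (syh**2).sum())
        assert m.rmse == pytest.approx(rmse, abs=1e-12)
        assert m.r2 == pytest.approx(r * r, abs=1e-12)


class TestCrossValidate:
    def test_interpolating_model_near_zero(self, rng):
        X, y = linear_data(rng, n=50)
        m = cross_validate(ModelSpec("mlr"), X, y, CVConfig(folds=5, repeats=2, seed=0))
        assert m.rmse < 1e-8

    def test_same_seed_identical(self, rng):
        X, y = linear_data(rng, noise=0.5)
        cv = CVConfig(folds=5, repeats=2, seed=3)
        a = cross_validate(ModelSpec("rf", {"mtry": 2, "n_trees": 20}, seed=1), X, y, cv)
        b = cross_validate(ModelSpec("rf", {"mtry": 2, "n_trees": 20}, seed=1), X, y, cv)
        assert a.rmse == b.rmse and a.r2 == b.r2

    def test_constant_predictor_matches_fold_oracle(self, rng):
        """MLR on a constant feature predicts the fold-training mean; the CV
        RMSE must match an explicit per-fold recomputation (~ sd of y)."""
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        X = pd.DataFrame({"c": np.ones(10), "c2": np.ones(10)})
        cv = CVConfig(folds=5, repeats=1, seed=7)
        got = cross_validate(ModelSpec("mlr"), X, y, cv).rmse
        from sklearn.model_selection import RepeatedKFold

        expected = []
        for tr, te in RepeatedKFold(n_splits=5, n_repeats=1, random_state=7).split(y):
            expected.append(np.sqrt(np.mean((y[te] - y[tr].mean()) ** 2)))
        assert got == pytest.approx(np.mean(expected), abs=1e-10)
        assert got == pytest.approx(np.std(y), rel=0.35)

    def test_folds_exceeding_rows_rejected(self, rng):
        X, y = linear_data(rng, n=4)
        with pytest.raises(ValueError):
            cross_validate(ModelSpec("mlr"), X, y, CVConfig(folds=10, repeats=1, seed=0))


class TestTune:
    def test_singleton_grid(self, rng):
        X, y = linear_data(rng, noise=0.3)
        spec = tune_model("pls", [{"ncomp": 2}], X, y, CVConfig(5, 1, 0))
        assert spec.hyperparams == {"ncomp": 2}

    def test_tie_goes_to_first(self, rng):
        X, y = linear_data(rng, noise=0.3)
        grid = [{"ncomp": 2}, {"ncomp": 2}]
        spec = tune_model("pls", grid, X, y, CVConfig(5, 1, 0))
        assert spec.hyperparams is not grid[1] and spec.hyperparams == {"ncomp": 2}

    def test_argmin_contract(self, rng):
        X, y = linear_data(rng, n=80, noise=0.3)
        cv = CVConfig(5, 1, 0)
        grid = [{"ncomp": 1}, {"ncomp": 2}, {"ncomp": 4}]
        best = tune_model("pls", grid, X, y, cv)
        best_rmse = cross_validate(best, X, y, cv).rmse
        for point in grid:
            other = cross_validate(ModelSpec("pls", point), X, y, cv).rmse
            assert best_rmse <= other + 1e-12


class TestEnsemble:
    def test_prediction_is_affine_in_base_predictions(self, rng):
        X, y = linear_data(rng, n=80, noise=0.3)
        ens = train_ensemble(
            X, y,
            base_specs=[ModelSpec("svm_rbf"), ModelSpec("rf", {"mtry": 2, "n_trees": 20}, 0),
                        ModelSpec("gbm", {"n_trees": 20}, 0)],
            cv=CVConfig(5, 1, 0),
        )
        P = ens.base_predictions(X)
        assert np.allclose(ens.predict(X), ens.intercept_ + P @ ens.weights_)

    def test_perfect_base_dominates_meta_weights(self, rng):
        n = 150
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        y = X.to_numpy() @ np.array([1.0, -2.0, 0.5])
        # mlr interpolates exactly; the two forests are noisy approximators
        ens = train_ensemble(
            X, y,
            base_specs=[ModelSpec("mlr"), ModelSpec("rf", {"mtry": 2, "n_trees": 10}, 0),
                        ModelSpec("gbm", {"n_trees": 5}, 0)],
            cv=CVConfig(5, 1, 0),
        )
        assert ens.weights_[0] == pytest.approx(1.0, abs=0.05)
        assert evaluate(y, ens.predict(X)).rmse < 0.05

    def test_identical_bases_give_invariant_prediction(self, rng):
        X, y = linear_data(rng, n=60, noise=0.4)
        spec = ModelSpec("rf", {"mtry": 2, "n_trees": 20}, seed=9)
        with pytest.warns(UserWarning, match="degenerate"):
            ens = train_ensemble(X, y, base_specs=[spec, spec, spec], cv=CVConfig(5, 1, 0))
        assert ens.degenerate_
        base = ens.base_models_[0].predict(X)
        combined = ens.intercept_ + base * ens.weights_.sum()
        assert np.allclose(ens.predict(X), combined)

    def test_matches_sklearn_stacking_cross_check(self, rng):
        """Same OOF folds + linear meta-model as sklearn's StackingRegressor."""
        X, y = linear_data(rng, n=120, p=5, noise=0.5)
        folds = KFold(5, shuffle=True, random_state=21)
        bases = {
            "svm": SVR(kernel="rbf", gamma=0.015, C=2.0, epsilon=0.1),
            "rf": RandomForestRegressor(n_estimators=30, max_features=2, random_state=3),
            "gbm": GradientBoostingRegressor(n_estimators=30, max_depth=3, random_state=3),
        }
        sk = StackingRegressor(
            estimators=list(bases.items()), final_estimator=LinearRegression(), cv=folds
        ).fit(X.to_numpy(), y)

        ours = StackingEnsemble(
            base_specs=[
                ModelSpec("svm_rbf"),
                ModelSpec("rf", {"mtry": 2, "n_trees": 30}, seed=3),
                ModelSpec("gbm", {"n_trees": 30, "interaction_depth": 3,
                                  "min_node_obs": 1}, seed=3),
            ],
            cv=CVConfig(folds=5, repeats=1, seed=21),
        ).fit(X, y)
        # same procedure, independent implementation: predictions agree closely
        assert np.corrcoef(sk.predict(X.to_numpy()), ours.predict(X))[0, 1] > 0.999
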