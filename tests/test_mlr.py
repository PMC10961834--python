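"""Hold-out splitting, no-intercept OLS, metrics, prediction, collinearity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aromatherm.mlr import (
    GCDataset,
    MulticollinearityError,
    collinearity_report,
    fit_ols,
    holdout_split,
    metrics,
    predict,
)
from aromatherm.quantities import ThermoError
from aromatherm.synthetic import SimulationSpec, gen_gc_dataset

W_TRUE = {f"g{i}": 15.0 * (i + 1) for i in range(5)}


def _dataset(n=20, seed=0, noise=0.0, **kw):
    ds, _ = gen_gc_dataset(W_TRUE, SimulationSpec(seed=seed, n=n, noise_sd=noise), **kw)
    return ds


class TestHoldout:
    @pytest.mark.parametrize("n,n_train,n_test", [(55, 38, 17), (67, 46, 21), (10, 7, 3)])
    def test_split_sizes_use_ceiling_on_test(self, n, n_train, n_test):
        ds = _dataset(n=n)
        train, test = holdout_split(ds, 0.3, seed=98)
        assert (train.n, test.n) == (n_train, n_test)

    def test_deterministic_and_disjoint(self):
        ds = _dataset(n=10)
        t1 = holdout_split(ds, 0.3, seed=5)
        t2 = holdout_split(ds, 0.3, seed=5)
        assert t1[0].molecules == t2[0].molecules
        assert t1[1].molecules == t2[1].molecules
        assert set(t1[0].molecules).isdisjoint(t1[1].molecules)
        assert set(t1[0].molecules) | set(t1[1].molecules) == set(ds.molecules)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ThermoError):
            holdout_split(_dataset(n=10), 1.5, seed=0)


class TestFitOls:
    def test_noiseless_recovery(self):
        ds = _dataset(n=30)
        res = fit_ols(ds)
        for f, w in W_TRUE.items():
            assert res.weights[f] == pytest.approx(w, abs=1e-9)
        assert res.dropped_features == ()

    def test_hand_solved_normal_equations(self):
        # 3 molecules x 2 features; solve (X'X) w = X'y by hand:
        # X'X = [[5, 4], [4, 6]], X'y = [11, 12], det = 14
        # w1 = (66 - 48)/14 = 9/7, w2 = (60 - 44)/14 = 8/7
        X = np.array([[1.0, 2.0], [2.0, 1.0], [0.0, 1.0]])
        y = np.array([3.0, 4.0, 2.0])
        ds = GCDataset(("a", "b", "c"), ("f1", "f2"), X, y)
        res = fit_ols(ds)
        assert res.weights["f1"] == pytest.approx(9 / 7, rel=1e-12)
        assert res.weights["f2"] == pytest.approx(8 / 7, rel=1e-12)

    def test_duplicate_column_dropped_then_fit_proceeds(self):
        ds = _dataset(n=30, inject_alias=True)
        res = fit_ols(ds)
        assert res.dropped_features == ("g0_alias",)
        assert res.weights["g0"] == pytest.approx(W_TRUE["g0"], abs=1e-9)

    def test_rank_deficiency_beyond_aliasing_is_detected(self):
        # fewer rows than independent columns cannot be full rank
        X = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 3.0]])
        ds = GCDataset(("a", "b"), ("f1", "f2", "f3"), X, np.array([1.0, 2.0]))
        res = fit_ols(ds)  # third column aliased by prefix-greedy rule
        assert "f3" in res.dropped_features

    def test_matches_normal_equations_on_100_random_systems(self):
        """OLS weights equal the brute-force normal-equations solution."""
        rng = np.random.default_rng(12345)
        for _ in range(100):
            n, p = int(rng.integers(8, 40)), int(rng.integers(2, 7))
            X = rng.normal(size=(n, p)) + 1.0
            while np.linalg.matrix_rank(X) < p or np.any(~X.any(axis=1)):
                X = rng.normal(size=(n, p)) + 1.0
            y = rng.normal(size=n)
            feats = tuple(f"f{j}" for j in range(p))
            ds = GCDataset(tuple(f"m{i}" for i in range(n)), feats, X, y)
            res = fit_ols(ds)
            w_oracle = np.linalg.solve(X.T @ X, X.T @ y)
            w_fit = np.array([res.weights[f] for f in feats])
            assert np.allclose(w_fit, w_oracle, rtol=1e-8, atol=1e-10)

    def test_intercept_with_constant_column_is_multicollinear(self):
        # a constant feature column survives alias dropping but duplicates
        # the explicit intercept column
        X = np.column_stack([np.ones(6), np.arange(6, dtype=float) + 1])
        ds = GCDataset(
            tuple(f"m{i}" for i in range(6)), ("const", "f1"), X,
            np.arange(6, dtype=float),
        )
        with pytest.raises(MulticollinearityError):
            fit_ols(ds, intercept=True)

    def test_optional_intercept_fits_offset(self):
        X = np.arange(1, 9, dtype=float).reshape(-1, 1)
        y = 3.0 * X[:, 0] + 5.0
        ds = GCDataset(tuple(f"m{i}" for i in range(8)), ("f1",), X, y)
        res = fit_ols(ds, intercept=True)
        assert res.weights["f1"] == pytest.approx(3.0, abs=1e-9)
        assert res.intercept == pytest.approx(5.0, abs=1e-9)

    def test_train_metrics_beat_test_on_average(self):
        gaps = []
        for seed in range(20):
            ds = _dataset(n=40, seed=seed, noise=2.0)
            train, test = holdout_split(ds, 0.3, seed=seed)
            res = fit_ols(train, test, seed=seed)
            gaps.append(res.metrics_test["RMSE"] - res.metrics_train["RMSE"])
        assert np.mean(gaps) > 0


class TestMetrics:
    def test_perfect_prediction(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m["R2"], m["MAE"], m["RMSE"]) == (1.0, 0.0, 0.0)

    def test_hand_case(self):
        m = metrics([0.0, 2.0], [1.0, 1.0])
        assert m["R2"] == pytest.approx(0.0)
        assert m["MAE"] == pytest.approx(1.0)
        assert m["RMSE"] == pytest.approx(1.0)

    @given(
        st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=2,
            max_size=30,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_rmse_dominates_mae(self, pairs):
        y_true = [p[0] for p in pairs]
        y_pred = [p[1] for p in pairs]
        if np.allclose(y_true, y_true[0]):
            return
        m = metrics(y_true, y_pred)
        assert m["RMSE"] >= m["MAE"] - 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ThermoError):
            metrics([2.0, 2.0], [1.0, 3.0])


class TestPredict:
    def test_zero_vector_is_zero(self):
        res = fit_ols(_dataset(n=30))
        assert predict(res, {}) == 0.0

    def test_training_molecule_reproduced_noiselessly(self):
        ds = _dataset(n=30)
        res = fit_ols(ds)
        counts = {f: ds.X[0, j] for j, f in enumerate(ds.features)}
        assert predict(res, counts) == pytest.approx(ds.y[0], abs=1e-8)

    def test_heldout_molecule_exact_under_noiseless_fit(self):
        ds = _dataset(n=30)
        train, test = holdout_split(ds, 0.3, seed=1)
        res = fit_ols(train)
        counts = {f: test.X[0, j] for j, f in enumerate(test.features)}
        assert predict(res, counts) == pytest.approx(test.y[0], abs=1e-8)

    def test_unseen_feature_is_extrapolation_error(self):
        res = fit_ols(_dataset(n=30))
        with pytest.raises(ThermoError, match="novel"):
            predict(res, {"novel": 2})


class TestCollinearity:
    def test_orthogonal_design_condition_one(self):
        X = np.vstack([np.eye(3), np.eye(3)])
        ds = GCDataset(
            tuple("abcdef"), ("f1", "f2", "f3"), X, np.arange(6, dtype=float) + 1
        )
        rep = collinearity_report(ds)
        assert rep["condition_number"] == pytest.approx(1.0)
        assert rep["aliased_sets"] == []

    def test_duplicate_column_reported_as_aliased_pair(self):
        ds = _dataset(n=30, inject_alias=True)
        rep = collinearity_report(ds)
        assert ("g0", "g0_alias") in rep["aliased_sets"]

    def test_near_duplicate_flagged(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(1, 5, size=200)
        b = a + rng.normal(0, 0.01, size=200)  # rho ~ 0.999
        X = np.column_stack([a, b, rng.uniform(1, 5, size=200)])
        ds = GCDataset(
            tuple(f"m{i}" for i in range(200)), ("f1", "f2", "f3"), X,
            rng.normal(size=200),
        )
        rep = collinearity_report(ds)
        assert any({"f1", "f2"} == {p[0], p[1]} for p in rep["flagged_pairs"])
        assert rep["max_pairwise_correlation"] > 0.99


class TestWeightRecovery:
    def test_recovery_within_3se_in_90pct_of_replicates(self):
        """At sigma=2 kJ/mol, n=55: all weights within 3 SE in >= 90% of fits."""
        w_true = {f"g{i}": 10.0 + 7.0 * i for i in range(8)}
        hits = 0
        for seed in range(100):
            ds, _ = gen_gc_dataset(w_true, SimulationSpec(seed=seed, n=55, noise_sd=2.0))
            res = fit_ols(ds)
            X, y = ds.X, ds.y
            w_hat = np.array([res.weights[f] for f in ds.features])
            resid = y - X @ w_hat
            sigma2 = resid @ resid / (len(y) - X.shape[1])
            se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
            truth = np.array([w_true[f] for f in ds.features])
            if np.all(np.abs(w_hat - truth) <= 3 * se):
                hits += 1
        assert hits >= 90

    def test_noiseless_end_to_end_metrics(self):
        ds = _dataset(n=55, seed=98)
        train, test = holdout_split(ds, 0.3, seed=98)
        res = fit_ols(train, test, seed=98)
        assert res.metrics_test["R2"] == pytest.approx(1.0, abs=1e-9)
        assert res.metrics_test["MAE"] == pytest.approx(0.0, abs=1e-7)
        assert res.metrics_test["RMSE"] == pytest.approx(0.0, abs=1e-7)
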