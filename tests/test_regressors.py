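import numpy as np
import pytest

from thznitro.chemometrics import r_squared, rmse
from thznitro.io_formats import SpectraSet
from thznitro.partitioning import SplitResult, ks_split
from thznitro.regressors import (
    BPNNModel,
    bpnn_predict,
    bpnn_train,
    evaluate_model,
    rbf_predict,
    rbf_spread_sweep,
    rbf_train,
)
from thznitro.regressors import _minmax_scale, _minmax_unscale


class TestRbfTrain:
    def test_exact_design_interpolates_for_every_spread(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        for spread in np.arange(0.1, 1.01, 0.1):
            model = rbf_train(X, y, float(spread))
            assert rmse(y, rbf_predict(model, X)) < 1e-6

    def test_single_center_fits_one_point(self):
        model = rbf_train([[1.0, 2.0]], [3.5], spread=0.7)
        assert rbf_predict(model, [[1.0, 2.0]])[0] == pytest.approx(3.5, abs=1e-9)

    def test_two_samples_match_hand_solved_system(self):
        # centers x1=0, x2=1, spread s: A = [[1, a],[a, 1]] with
        # a = exp(-(0.8326/s)^2); system [A | 1] w = y is underdetermined, so
        # verify the package solution reproduces y exactly and satisfies the
        # normal-equations optimality of the min-norm least-squares solve
        s = 0.5
        y = np.array([1.0, 2.0])
        model = rbf_train([[0.0], [1.0]], y, s)
        a = np.exp(-((0.8326 / s) ** 2))
        A_aug = np.array([[1.0, a, 1.0], [a, 1.0, 1.0]])
        sol = np.concatenate([model.weights, [model.bias]])
        np.testing.assert_allclose(A_aug @ sol, y, atol=1e-9)
        expect = np.linalg.lstsq(A_aug, y, rcond=None)[0]
        np.testing.assert_allclose(sol, expect, atol=1e-9)

    def test_invalid_spread_rejected(self):
        with pytest.raises(ValueError):
            rbf_train([[0.0], [1.0]], [1.0, 2.0], spread=0.0)


class TestRbfPredict:
    def test_tiny_spread_localizes_to_center_value(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        model = rbf_train(X, y, spread=1e-3)
        np.testing.assert_allclose(rbf_predict(model, X), y, atol=1e-6)

    def test_continuous_in_spread(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        x_new = rng.normal(size=(1, 4))
        eps = 1e-6
        lo = rbf_predict(rbf_train(X, y, 0.5 - eps), x_new)[0]
        hi = rbf_predict(rbf_train(X, y, 0.5 + eps), x_new)[0]
        assert abs(hi - lo) < 1e-3

    def test_center_order_irrelevant(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        perm = rng.permutation(8)
        x_new = rng.normal(size=(3, 3))
        a = rbf_predict(rbf_train(X, y, 0.6), x_new)
        b = rbf_predict(rbf_train(X[perm], y[perm], 0.6), x_new)
        np.testing.assert_allclose(a, b, atol=1e-7)

    def test_dimension_mismatch_rejected(self, rng):
        model = rbf_train(rng.normal(size=(4, 3)), rng.normal(size=4), 0.5)
        with pytest.raises(ValueError):
            rbf_predict(model, rng.normal(size=(2, 5)))


class TestRbfSpreadSweep:
    def test_default_sweep_covers_point_one_to_one(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        out = rbf_spread_sweep(X, y)
        np.testing.assert_allclose(out["spreads"], np.arange(0.1, 1.01, 0.1), atol=1e-9)

    def test_single_spread_single_row(self, rng):
        out = rbf_spread_sweep(rng.normal(size=(6, 2)), rng.normal(size=6), [0.4])
        assert out["spreads"].shape == (1,)
        assert out["best_spread"] == 0.4

    def test_rows_match_independent_recomputation(self, rng):
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        out = rbf_spread_sweep(X, y, [0.3, 0.7])
        for s, r in zip(out["spreads"], out["rmsec"]):
            model = rbf_train(X, y, float(s))
            assert r == pytest.approx(rmse(y, rbf_predict(model, X)), abs=1e-12)

    def test_validated_sweep_selects_by_holdout(self, rng):
        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, -0.5, 0.3]) + 0.05 * rng.normal(size=20)
        out = rbf_spread_sweep(X, y, cv_indices=(np.arange(14), np.arange(14, 20)))
        assert "rmse_val" in out
        k = int(np.argmin(out["rmse_val"]))
        assert out["best_spread"] == out["spreads"][k]


class TestBpnn:
    def test_learns_noiseless_linear_map(self, rng):
        X = rng.uniform(-1, 1, size=(40, 1))
        y = 2.0 * X[:, 0] + 1.0
        params = BPNNModel(hidden_size=6, learning_rate=0.05, max_epochs=5000)
        model = bpnn_train(X, y, params, seed=0)
        assert r_squared(y, bpnn_predict(model, X)) >= 0.99

    def test_loss_non_increasing_under_small_rate(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ np.array([0.5, -1.0, 0.2, 0.8])
        params = BPNNModel(hidden_size=4, learning_rate=0.001, max_epochs=200)
        model = bpnn_train(X, y, params, seed=1)
        assert np.all(np.diff(model.loss_curve) <= 1e-12)

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        a = bpnn_train(X, y, seed=3)
        b = bpnn_train(X, y, seed=3)
        np.testing.assert_array_equal(a.w1, b.w1)
        np.testing.assert_array_equal(a.w2, b.w2)
        c = bpnn_train(X, y, seed=4)
        assert not np.array_equal(a.w1, c.w1)

    def test_hand_computed_single_unit_forward_pass(self):
        model = BPNNModel(hidden_size=1)
        model.w1 = np.array([[0.5]])
        model.b1 = np.array([0.1])
        model.w2 = np.array([2.0])
        model.b2 = 0.25
        model.x_min, model.x_max = np.array([0.0]), np.array([2.0])
        model.y_min, model.y_max = 0.0, 10.0
        # x=1 -> scaled 0; hidden tanh(0.1); out 2*tanh(0.1)+0.25; unscale
        expect = (2.0 * np.tanh(0.1) + 0.25 + 1.0) / 2.0 * 10.0
        assert bpnn_predict(model, [[1.0]])[0] == pytest.approx(expect, rel=1e-12)

    def test_scaler_round_trip(self, rng):
        v = rng.normal(size=20)
        lo, hi = v.min(), v.max()
        np.testing.assert_allclose(_minmax_unscale(_minmax_scale(v, lo, hi), lo, hi), v)

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError):
            bpnn_train(rng.normal(size=(8, 2)), np.ones(8))

    def test_dimension_mismatch_rejected(self, rng):
        model = bpnn_train(rng.normal(size=(10, 3)), rng.normal(size=10), seed=0)
        with pytest.raises(ValueError):
            bpnn_predict(model, rng.normal(size=(2, 7)))


class TestEvaluateModel:
    def _data(self, rng, n=12, p=4):
        X = rng.normal(size=(n, p))
        return SpectraSet(
            frequencies_thz=np.linspace(0.05, 1.35, p),
            power=X,
            nitrogen_pct=np.abs(X[:, 0]) + 1.0,
            sample_ids=[f"s{i}" for i in range(n)],
        )

    def test_perfect_model_scores_perfectly(self, rng):
        data = self._data(rng)
        split = ks_split(data, 8)

        class Perfect:
            def predict(self_inner, X):
                return np.abs(X[:, 0]) + 1.0

        rep = evaluate_model(Perfect(), data, split, None, "oracle", "none")
        assert (rep.rmsec_pct, rep.r2_cal, rep.rmsep_pct, rep.r2_pred) == (0.0, 1.0, 0.0, 1.0)
        assert rep.n_cal + rep.n_pred == data.n_samples

    def test_fields_match_independent_metric_recomputation(self, rng):
        data = self._data(rng)
        split = ks_split(data, 8)
        sel = np.array([0, 2])
        model = rbf_train(data.power[split.cal_indices][:, sel],
                          data.nitrogen_pct[split.cal_indices], 0.8)
        rep = evaluate_model(model, data, split, sel, "rbf", "manual")
        y_pred = data.nitrogen_pct[split.pred_indices]
        yhat = rbf_predict(model, data.power[split.pred_indices][:, sel])
        assert rep.rmsep_pct == pytest.approx(rmse(y_pred, yhat))
        assert rep.r2_pred == pytest.approx(r_squared(y_pred, yhat))

    def test_pure_function_repeated_calls_identical(self, rng):
        data = self._data(rng)
        split = ks_split(data, 8)
        model = rbf_train(data.power[split.cal_indices], data.nitrogen_pct[split.cal_indices], 0.5)
        a = evaluate_model(model, data, split, None)
        b = evaluate_model(model, data, split, None)
        assert a == b

    def test_empty_prediction_set_rejected(self, rng):
        data = self._data(rng)
        split = SplitResult(cal_indices=list(range(12)), pred_indices=[], method="KS")
        model = rbf_train(data.power, data.nitrogen_pct, 0.5)
        with pytest.raises(ValueError):
            evaluate_model(model, data, split, None)
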