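"""Kernel regression machinery: dual solve, CV search, selection, splits."""

import numpy as np
import pytest

from firecarb import svr


def make_xy(rng, n=30, p=3, noise=0.1):
    X = rng.normal(size=(n, p))
    y = 2.0 * X[:, 0] + np.sin(X[:, 1]) + noise * rng.normal(size=n)
    return X, y


def dense_oracle(X, y, h, gamma, Xq):
    """Independent construction of the LS-SVM solution and predictions."""
    X = np.asarray(X, float)
    mean, sd = X.mean(0), X.std(0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd
    Xqs = (np.asarray(Xq, float) - mean) / sd
    n = Xs.shape[0]

    def kernel(A, B):
        d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
        return np.exp(-d2 / h**2)

    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1
    A[1:, 0] = 1
    A[1:, 1:] = kernel(Xs, Xs) + np.eye(n) / gamma
    sol = np.linalg.lstsq(A, np.concatenate(([0.0], y)), rcond=None)[0]
    return kernel(Xqs, Xs) @ sol[1:] + sol[0]


class TestTrainLSSVR:
    def test_matches_dense_linear_algebra_oracle(self, rng):
        for n in (5, 20, 50):
            X, y = make_xy(rng, n=n)
            Xq = rng.normal(size=(10, 3))
            model = svr.train_lssvr(X, y, h=2.0, gamma=50.0)
            np.testing.assert_allclose(model.predict(Xq),
                                       dense_oracle(X, y, 2.0, 50.0, Xq),
                                       atol=1e-8)

    def test_interpolates_in_large_penalty_limit(self, rng):
        X, y = make_xy(rng, n=5, noise=0.0)
        model = svr.train_lssvr(X, y, h=1.0, gamma=1e10)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-4)

    def test_constant_response_reproduced_by_bias(self, rng):
        X = rng.normal(size=(8, 2))
        y = np.full(8, 7.5)
        model = svr.train_lssvr(X, y, h=1.0, gamma=10.0)
        assert model.bias == pytest.approx(7.5, abs=1e-6)
        np.testing.assert_allclose(model.predict(rng.normal(size=(4, 2))),
                                   7.5, atol=1e-6)

    def test_prediction_invariant_under_affine_input_rescaling(self, rng):
        X, y = make_xy(rng)
        Xq = rng.normal(size=(6, 3))
        scale = np.array([3.0, 0.5, 10.0])
        shift = np.array([1.0, -4.0, 0.2])
        m1 = svr.train_lssvr(X, y, 2.0, 20.0)
        m2 = svr.train_lssvr(X * scale + shift, y, 2.0, 20.0)
        np.testing.assert_allclose(m1.predict(Xq),
                                   m2.predict(Xq * scale + shift), atol=1e-8)


class TestGridSearch:
    def test_single_point_grid_returned(self, rng):
        X, y = make_xy(rng, n=20)
        h, g, rows, model = svr.grid_search_cv(X, y, h_grid=[1.5],
                                               gamma_grid=[7.0], k=5)
        assert (h, g) == (1.5, 7.0)
        assert len(rows) == 1

    def test_same_seed_same_selection(self, rng):
        X, y = make_xy(rng, n=40, noise=0.5)
        grid = np.geomspace(0.3, 10, 5)
        a = svr.grid_search_cv(X, y, grid, grid, k=5, seed=3)[:2]
        b = svr.grid_search_cv(X, y, grid, grid, k=5, seed=3)[:2]
        assert a == b

    def test_recovers_bandwidth_regime_for_planted_function(self, rng):
        # smooth 1-D function: CV should reject the extreme bandwidths
        X = rng.uniform(-3, 3, size=(120, 1))
        y = np.sin(X[:, 0]) + 0.05 * rng.normal(size=120)
        h_grid = np.geomspace(0.01, 100, 7)
        h, g, rows, model = svr.grid_search_cv(X, y, h_grid, [100.0], k=10,
                                               seed=0)
        assert 0.05 < h < 30.0
        resid = model.predict(X) - y
        assert np.sqrt((resid**2).mean()) < 0.2

    def test_too_few_samples_for_folds(self, rng):
        X, y = make_xy(rng, n=6)
        with pytest.raises(ValueError):
            svr.grid_search_cv(X, y, [1.0], [1.0], k=10)


class TestFeatureSelect:
    def test_expert_subset_returned_verbatim(self):
        names = ["H50", "AUCW", "mean_h"]
        out = svr.feature_select(np.zeros((5, 3)), np.zeros(5), names,
                                 method="expert",
                                 expert_subset=svr.EXPERT_FEATURES_LIDAR)
        assert out == ["AUCW", "H50"]

    def test_stepwise_finds_planted_signal(self, rng):
        n = 80
        X = rng.normal(size=(n, 5))
        y = 3.0 * X[:, 2] + 0.2 * rng.normal(size=n)
        names = [f"f{i}" for i in range(5)]
        out = svr.feature_select(X, y, names, method="stepwise")
        assert out[0] == "f2"

    def test_evolutionary_is_seeded_deterministic(self, rng):
        X = rng.normal(size=(40, 4))
        y = X[:, 0] + rng.normal(size=40)
        names = list("abcd")
        a = svr.feature_select(X, y, names, method="evolutionary", seed=5,
                               population=6, generations=3)
        b = svr.feature_select(X, y, names, method="evolutionary", seed=5,
                               population=6, generations=3)
        assert a == b and len(a) >= 1

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            svr.feature_select(np.zeros((4, 2)), np.zeros(4), ["a", "b"],
                               method="magic")


class TestFitMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        fit = svr.fit_metrics(y, y, p=1)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = svr.fit_metrics(y, np.full(5, y.mean()), p=1)
        assert fit.r2 == pytest.approx(0.0)

    def test_relative_rmse_matches_field_study_scale(self, rng):
        # plots averaging 195.8 Mg/ha with RMSE 59.98 -> relRMSE 30.63%
        n = 4000
        y = np.full(n, 195.8)
        e = rng.normal(size=n)
        e = 59.98 * e / np.sqrt((e**2).mean())
        fit = svr.fit_metrics(y + e, y, p=2)
        assert fit.rel_rmse_pct == pytest.approx(
            100 * 59.98 / (y + e).mean(), rel=1e-9)
        assert fit.rel_rmse_pct == pytest.approx(30.63, abs=0.5)

    def test_constant_observations_signalled(self):
        with pytest.raises(svr.DegenerateResponseError):
            svr.fit_metrics(np.ones(5), np.zeros(5), p=1)


class TestSplit:
    def test_field_study_sample_split_sizes(self, rng):
        y = rng.normal(size=514)
        cal, val = svr.split_calibration_validation(y, 0.7, seed=0)
        assert cal.size == 360 and val.size == 154
        assert np.array_equal(np.sort(np.concatenate([cal, val])),
                              np.arange(514))

    def test_stratification_balances_deciles(self, rng):
        y = np.sort(rng.normal(size=200))
        cal, _ = svr.split_calibration_validation(y, 0.7, seed=1)
        top = np.sum(cal >= 180)  # top decile share
        assert 10 <= top <= 18

    def test_full_fraction_flags_empty_validation(self, rng):
        y = rng.normal(size=20)
        with pytest.warns(UserWarning):
            cal, val = svr.split_calibration_validation(y, 1.0, seed=0)
        assert val.size == 0

    def test_same_seed_identical(self, rng):
        y = rng.normal(size=50)
        a = svr.split_calibration_validation(y, 0.7, seed=4)
        b = svr.split_calibration_validation(y, 0.7, seed=4)
        assert np.array_equal(a[0], b[0])


class TestHistogramSample:
    def test_sample_exhausts_mask_when_sizes_match(self, rng):
        agb = rng.random((10, 10)) * 300
        mask = np.zeros((10, 10), bool)
        mask[:5] = True
        out = svr.stratified_histogram_sample(agb, mask, n=50, seed=0)
        assert np.array_equal(out, np.flatnonzero(mask.ravel()))

    def test_all_draws_inside_mask(self, rng):
        agb = rng.random((20, 20)) * 300
        mask = rng.random((20, 20)) > 0.3
        out = svr.stratified_histogram_sample(agb, mask, n=100, seed=1)
        assert mask.ravel()[out].all()
        assert out.size == 100
        assert np.unique(out).size == 100

    def test_sample_covers_biomass_range(self, rng):
        agb = rng.lognormal(5.0, 0.6, size=(40, 40))
        mask = np.ones((40, 40), bool)
        out = svr.stratified_histogram_sample(agb, mask, n=200, seed=2)
        vals = agb.ravel()[out]
        full = agb.max() - agb.min()
        assert (vals.max() - vals.min()) >= 0.95 * full
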