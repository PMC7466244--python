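import numpy as np
import pytest

from ramcal import (cross_validate, fit_pls1, predict, regression_metrics,
                    venetian_blinds_indices)

from .oracles import ols_fit_predict, pls1_oracle_coefs, pls1_oracle_predict


class TestFitPLS1:
    def test_rank_one_single_factor_exact(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=12)
        v = rng.normal(size=6)
        X = np.outer(u, v)
        y = X @ rng.normal(size=6)
        model = fit_pls1(X, y, 1)
        assert np.allclose(predict(model, X), y, atol=1e-10)

    def test_matches_krylov_oracle(self, rng):
        X = rng.normal(size=(20, 50))
        y = rng.normal(size=20)
        model = fit_pls1(X, y, 3)
        assert np.abs(model.coefs[:, 2] - pls1_oracle_coefs(X, y, 3)).max() < 1e-8

    def test_matches_sklearn_nipals(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(25, 40))
        y = rng.normal(size=25)
        model = fit_pls1(X, y, 4)
        sk = sklearn.PLSRegression(n_components=4, scale=False).fit(X, y)
        assert np.allclose(model.coefs[:, 3], sk.coef_.ravel(), atol=1e-10)

    def test_full_rank_limit_equals_ols(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        model = fit_pls1(X, y, 5)
        assert np.allclose(predict(model, X), ols_fit_predict(X, y, X), atol=1e-6)

    def test_weight_columns_unit_norm(self, rng):
        model = fit_pls1(rng.normal(size=(15, 30)), rng.normal(size=15), 4)
        assert np.allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-12)

    def test_scores_mutually_orthogonal(self, rng):
        model = fit_pls1(rng.normal(size=(25, 60)), rng.normal(size=25), 5)
        G = model.T.T @ model.T
        norms = np.sqrt(np.diag(G))
        off = G / np.outer(norms, norms) - np.eye(model.A)
        assert np.abs(off).max() < 1e-8

    def test_rmsec_non_increasing_in_components(self, rng):
        X = rng.normal(size=(30, 40))
        y = rng.normal(size=30)
        model = fit_pls1(X, y, 6)
        rmse = [regression_metrics(y, predict(model, X, a)).rmse
                for a in range(1, 7)]
        assert all(b <= a + 1e-12 for a, b in zip(rmse, rmse[1:]))

    def test_zero_variance_y_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pls1(rng.normal(size=(10, 5)), np.ones(10), 2)

    def test_excessive_components_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pls1(rng.normal(size=(10, 5)), rng.normal(size=10), 6)


class TestPredict:
    def test_mean_input_predicts_mean_response(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        model = fit_pls1(X, y, 3)
        Xm = np.tile(model.x_mean, (4, 1))
        assert np.allclose(predict(model, Xm), model.y_mean, atol=1e-10)

    def test_one_component_matches_oracle(self, rng):
        X = rng.normal(size=(18, 25))
        y = rng.normal(size=18)
        Xn = rng.normal(size=(5, 25))
        model = fit_pls1(X, y, 1)
        assert np.allclose(predict(model, Xn, 1),
                           pls1_oracle_predict(X, y, Xn, 1), atol=1e-8)

    def test_channel_mismatch_rejected(self, rng):
        model = fit_pls1(rng.normal(size=(10, 8)), rng.normal(size=10), 2)
        with pytest.raises(ValueError):
            predict(model, rng.normal(size=(3, 9)))


class TestVenetianBlinds:
    def test_interleaved_assignment(self):
        folds = venetian_blinds_indices(8, 4)
        for f in range(4):
            assert np.array_equal(np.flatnonzero(folds == f), [f, f + 4])

    def test_fold_sizes_83_10(self):
        folds = venetian_blinds_indices(83, 10)
        sizes = np.bincount(folds)
        assert sorted(sizes) == [8] * 7 + [9] * 3
        assert sizes.sum() == 83

    def test_loo_when_s_equals_n(self):
        assert np.array_equal(venetian_blinds_indices(5, 5), np.arange(5))

    def test_invalid_split_count(self):
        with pytest.raises(ValueError):
            venetian_blinds_indices(4, 5)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.r2, m.rmse, m.bias) == (1.0, 0.0, 0.0)

    def test_constant_shift(self):
        y = np.array([1.0, 2.0, 3.0])
        m = regression_metrics(y, y + 1.0)
        assert m.bias == 1.0 and m.rmse == 1.0 and m.r2 < 1.0

    def test_hand_computed_values(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert m.rmse == pytest.approx(np.sqrt(1.0 / 3.0))
        assert m.bias == pytest.approx(1.0 / 3.0)
        assert m.r2 == pytest.approx(0.5)

    def test_bias_bounded_by_rmse(self, rng):
        y, yh = rng.normal(size=50), rng.normal(size=50)
        m = regression_metrics(y, yh)
        assert m.bias**2 <= m.rmse**2 + 1e-12

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([2.0, 2.0], [1.0, 3.0])


class TestCrossValidate:
    def test_noiseless_signal_recovered(self, rng):
        # two latent factors drive both X and y; exact recovery needs
        # no more components than the predictor rank
        T = rng.normal(size=(40, 2))
        X = T @ rng.normal(size=(2, 10))
        y = 2.0 * T[:, 0] - 1.5 * T[:, 1]
        cv = cross_validate(X, y, A_max=4, s=10)
        assert cv.rmsecv[cv.chosen_A - 1] < 1e-6 * y.std()

    def test_permuted_response_has_no_skill(self):
        r2 = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(40, 10))
            y = 2.0 * X[:, 2] - 1.5 * X[:, 7]
            cv = cross_validate(X, r.permutation(y), A_max=3, s=10)
            r2.append(cv.r2cv[cv.chosen_A - 1])
        assert np.mean(r2) <= 0.1

    def test_loo_equals_brute_force(self, rng):
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        cv = cross_validate(X, y, A_max=2, s=6)
        for i in range(6):
            mask = np.arange(6) != i
            expected = pls1_oracle_predict(X[mask], y[mask], X[i], 2)
            assert cv.cv_predictions[i, 1] == pytest.approx(float(expected[0]),
                                                            abs=1e-8)

    def test_predictions_cover_each_sample_once(self, rng):
        X = rng.normal(size=(23, 12))
        y = rng.normal(size=23)
        cv = cross_validate(X, y, A_max=3, s=5)
        assert np.all(np.isfinite(cv.cv_predictions))
        assert np.bincount(cv.folds, minlength=5).sum() == 23

    def test_no_centering_leakage(self, rng):
        # adding a constant to held-out y must shift bias by that constant
        X = rng.normal(size=(30, 15))
        y = rng.normal(size=30)
        cv = cross_validate(X, y, A_max=3, s=10)
        shift = 5.0
        m = regression_metrics(y + shift, cv.cv_predictions[:, 2])
        base = regression_metrics(y, cv.cv_predictions[:, 2])
        assert m.bias == pytest.approx(base.bias - shift, abs=1e-10)

    def test_parsimony_prefers_smaller_a(self, rng):
        # rank-1 predictors: components beyond the first cannot help,
        # so the parsimony rule must settle on A = 1
        t = rng.normal(size=40)
        X = np.outer(t, rng.normal(size=10))
        y = t + 0.01 * rng.normal(size=40)
        cv = cross_validate(X, y, A_max=5, s=10)
        assert cv.chosen_A == 1

    def test_tiny_training_fold_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_validate(rng.normal(size=(4, 3)), rng.normal(size=4),
                           A_max=2, s=2)
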