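import numpy as np
import pytest

from starchspec import (
    evaluate,
    pls_fit,
    pls_predict,
    rank_order_split,
    rpd,
    select_lv_cv,
)


class TestRankOrderSplit:
    def test_96_samples_gives_64_32(self, rng):
        y = rng.normal(12, 4, size=96)
        split = rank_order_split(y)
        assert len(split.calibration_ids) == 64
        assert len(split.prediction_ids) == 32
        assert not set(split.calibration_ids) & set(split.prediction_ids)

    def test_middle_of_each_triplet(self):
        split = rank_order_split(np.array([1.0, 2, 3, 4, 5, 6]))
        assert split.prediction_ids == [1, 4]  # y values 2 and 5

    def test_prediction_range_inside_calibration_range(self, rng):
        y = rng.normal(0, 1, size=50)
        split = rank_order_split(y)
        assert min(y[split.prediction_ids]) > min(y[split.calibration_ids])
        assert max(y[split.prediction_ids]) < max(y[split.calibration_ids])

    def test_invariant_to_input_order_for_distinct_y(self, rng):
        y = rng.permutation(30).astype(float)
        ids = [f"s{v:.0f}" for v in y]
        perm = rng.permutation(30)
        split_a = rank_order_split(y, ids)
        split_b = rank_order_split(y[perm], [ids[i] for i in perm])
        assert set(split_a.prediction_ids) == set(split_b.prediction_ids)

    def test_leftover_samples_go_to_calibration(self):
        split = rank_order_split(np.arange(8.0))
        assert len(split.prediction_ids) == 2
        assert len(split.calibration_ids) == 6

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            rank_order_split(np.array([1.0, 2.0]))


class TestPLS:
    def test_full_lv_limit_equals_ols(self, rng):
        X = rng.standard_normal((20, 5))
        y = X @ rng.standard_normal(5) + rng.standard_normal(20)
        model = pls_fit(X, y, n_lv=5)
        beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(20), X]), y, rcond=None)
        ols_pred = np.column_stack([np.ones(20), X]) @ beta
        np.testing.assert_allclose(pls_predict(model, X), ols_pred, atol=1e-8)

    def test_noiseless_linear_fit_is_exact(self, rng):
        X = rng.standard_normal((25, 6))
        y = X @ np.array([1.0, -2, 0, 0.5, 3, 0])
        model = pls_fit(X, y, n_lv=6)
        assert np.sqrt(np.mean((pls_predict(model, X) - y) ** 2)) <= 1e-8

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.standard_normal((30, 8))
        y = X[:, 0] + 0.3 * rng.standard_normal(30)
        model = pls_fit(X, y, n_lv=5)
        Xs = (X - model.x_mean) / model.x_scale
        T = Xs @ model.W @ np.linalg.inv(model.P.T @ model.W)
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-10 * np.abs(np.diag(G)).max()

    def test_matches_sklearn_pls_oracle(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        for trial in range(5):
            rng2 = np.random.default_rng(100 + trial)
            X = rng2.standard_normal((20, 8))
            y = X @ rng2.standard_normal(8) + 0.5 * rng2.standard_normal(20)
            for k in (1, 3, 5):
                model = pls_fit(X, y, n_lv=k)
                ref = PLSRegression(n_components=k, scale=True).fit(X, y)
                np.testing.assert_allclose(
                    pls_predict(model, X), ref.predict(X).ravel(), atol=1e-8
                )

    def test_coefficient_form_matches_score_recursion(self, rng):
        X = rng.standard_normal((15, 6))
        y = X[:, 1] - X[:, 4] + 0.1 * rng.standard_normal(15)
        model = pls_fit(X, y, n_lv=4)
        # prediction via score recursion: t = Xs W (P'W)^-1, yhat = y_mean + t q
        Xs = (X - model.x_mean) / model.x_scale
        T = Xs @ model.W @ np.linalg.inv(model.P.T @ model.W)
        np.testing.assert_allclose(model.y_mean + T @ model.q, pls_predict(model, X), atol=1e-10)

    def test_predict_on_mean_row_returns_mean_response(self, rng):
        X = rng.standard_normal((18, 5))
        y = rng.standard_normal(18) + 4
        model = pls_fit(X, y, n_lv=3)
        assert pls_predict(model, X.mean(axis=0))[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_column_permutation_invariance(self, rng):
        X = rng.standard_normal((18, 5))
        y = X[:, 0] + rng.standard_normal(18)
        perm = rng.permutation(5)
        m1 = pls_fit(X, y, n_lv=3)
        m2 = pls_fit(X[:, perm], y, n_lv=3)
        Xn = rng.standard_normal((4, 5))
        np.testing.assert_allclose(pls_predict(m2, Xn[:, perm]), pls_predict(m1, Xn), atol=1e-10)

    def test_zero_variance_y_rejected(self, rng):
        with pytest.raises(ValueError):
            pls_fit(rng.standard_normal((10, 3)), np.ones(10), n_lv=2)

    def test_excessive_n_lv_rejected(self, rng):
        with pytest.raises(ValueError):
            pls_fit(rng.standard_normal((5, 3)), rng.standard_normal(5), n_lv=5)


class TestSelectLvCV:
    def test_simple_signal_picks_few_lvs(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((60, 10))
            y = 2 * X[:, 0] + rng.standard_normal(60)
            best, _ = select_lv_cv(X, y, max_lv=8, folds=5, seed=seed)
            hits += best <= 3
        assert hits >= 18

    def test_curve_length_is_effective_max(self, rng):
        X = rng.standard_normal((30, 6))
        y = X[:, 0] + rng.standard_normal(30)
        with pytest.warns(UserWarning, match="truncated"):
            _, curve = select_lv_cv(X, y, max_lv=15, folds=5, seed=0)
        assert curve.shape == (6,)

    def test_loo_matches_brute_force_loop(self):
        rng = np.random.default_rng(3)
        n = 15
        X = rng.standard_normal((n, 4))
        y = X @ np.array([1.0, 0.5, -1, 0]) + 0.3 * rng.standard_normal(n)
        best, curve = select_lv_cv(X, y, max_lv=4, folds=n, seed=7)
        # oracle: explicit leave-one-out loop (fold order does not matter)
        sq = np.zeros(4)
        for i in range(n):
            mask = np.arange(n) != i
            model = pls_fit(X[mask], y[mask], 4)
            for k in range(1, 5):
                sq[k - 1] += (pls_predict(model, X[i], n_lv=k)[0] - y[i]) ** 2
        np.testing.assert_allclose(curve, np.sqrt(sq / n), atol=1e-10)


class TestEvaluate:
    def test_perfect_model(self, rng):
        X = rng.standard_normal((24, 4))
        y = X @ np.array([2.0, -1, 0.5, 1])
        model = pls_fit(X, y, n_lv=4)
        rep = evaluate(model, X[:16], y[:16], X[16:], y[16:])
        assert rep.Rc == pytest.approx(1.0, abs=1e-8)
        assert rep.RMSEP == pytest.approx(0.0, abs=1e-7)

    def test_rpd_from_reported_statistics(self):
        assert round(rpd(4.71, 3.29), 2) == 1.43
        assert round(rpd(4.71, 2.53), 2) == 1.86

    def test_rpd_identity_holds_exactly(self, rng):
        X = rng.standard_normal((30, 5))
        y = X[:, 0] + 0.5 * rng.standard_normal(30)
        model = pls_fit(X[:20], y[:20], n_lv=3)
        rep = evaluate(model, X[:20], y[:20], X[20:], y[20:])
        assert rep.RPD * rep.RMSEP == pytest.approx(np.std(y[20:], ddof=1), abs=1e-12)

    def test_degenerate_reference_rejected(self, rng):
        X = rng.standard_normal((12, 3))
        y = X[:, 0] + 1
        model = pls_fit(X, y, n_lv=2)
        with pytest.raises(ValueError):
            evaluate(model, X, y, X[:3], np.full(3, 5.0))
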