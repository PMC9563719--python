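import math

import numpy as np
import pandas as pd
import pytest

from starchspec import (
    CARSConfig,
    cars_select,
    correlation_select,
    edf_ratio,
    fuse_low,
    fuse_mid,
)
from starchspec.selection import CARSResult, SelectionReport
from starchspec.texture import texture_feature_names


class TestEDF:
    def test_first_run_keeps_everything(self):
        assert edf_ratio(1, 50, 428) == pytest.approx(1.0, abs=1e-12)
        assert edf_ratio(1, 10, 30) == pytest.approx(1.0, abs=1e-12)

    def test_last_run_keeps_two_of_p(self):
        assert edf_ratio(50, 50, 428) == pytest.approx(2 / 428, abs=1e-12)

    def test_closed_form_midpoint(self):
        N, p, i = 50, 428, 25
        k = math.log(p / 2) / (N - 1)
        a = math.exp(k)
        assert edf_ratio(i, N, p) == pytest.approx(a * math.exp(-k * i), rel=1e-12)

    def test_small_p_rejected(self):
        with pytest.raises(ValueError):
            edf_ratio(1, 10, 2)


class TestCARS:
    def _planted(self, seed):
        rng = np.random.default_rng(1000 + seed)
        X = rng.standard_normal((60, 100))
        y = 3 * X[:, 10] - 2 * X[:, 50] + 0.2 * rng.standard_normal(60)
        return X, y

    def test_retained_counts_follow_edf_schedule(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((20, 30))
        y = X[:, 0] + rng.standard_normal(20)
        cfg = CARSConfig(n_runs=10, seed=0)
        res = cars_select(X, y, cfg)
        expected = [max(2, math.ceil(edf_ratio(i, 10, 30) * 30)) for i in range(1, 11)]
        assert res.retained_count_by_run.tolist() == expected
        assert np.all(np.diff(res.retained_count_by_run) <= 0)

    def test_deterministic_for_fixed_seed(self):
        X, y = self._planted(0)
        cfg = CARSConfig(n_runs=20, seed=123)
        a = cars_select(X, y, cfg)
        b = cars_select(X, y, cfg)
        np.testing.assert_array_equal(a.selected_indices, b.selected_indices)
        np.testing.assert_allclose(a.rmsecv_by_run, b.rmsecv_by_run)

    def test_recovers_planted_variables(self):
        hits = 0
        for seed in range(5):
            X, y = self._planted(seed)
            res = cars_select(X, y, CARSConfig(seed=seed))
            hits += {10, 50} <= set(res.selected_indices.tolist())
        assert hits >= 4

    def test_selection_is_argmin_run(self):
        # pure-noise predictors: selection must still return the argmin run,
        # with no spuriously large RMSECV improvement over the full model
        rng = np.random.default_rng(9)
        X = rng.standard_normal((40, 50))
        y = rng.standard_normal(40)
        res = cars_select(X, y, CARSConfig(n_runs=15, seed=2))
        assert res.best_run == int(np.argmin(res.rmsecv_by_run))
        assert res.rmsecv_by_run[res.best_run] > 0.5 * res.rmsecv_by_run[0]

    def test_selected_wavelengths_follow_indices(self):
        X, y = self._planted(1)
        wl = np.linspace(382, 1004, 100)
        res = cars_select(X, y, CARSConfig(n_runs=10, seed=4), wavelengths=wl)
        np.testing.assert_allclose(res.selected_wavelengths, wl[res.selected_indices])

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            cars_select(rng.standard_normal((5, 20)), rng.standard_normal(5), CARSConfig())


class TestCorrelationSelect:
    def test_identical_column_selected(self, rng):
        y = rng.standard_normal(20)
        T = pd.DataFrame({"same": y, "noise": rng.standard_normal(20)})
        rep = correlation_select(T, y)
        assert rep.texture_r["same"] == pytest.approx(1.0, abs=1e-12)
        assert "same" in rep.texture_selected

    def test_negated_shifted_column_selected(self, rng):
        y = rng.standard_normal(20)
        rep = correlation_select(pd.DataFrame({"neg": -y + 7}), y)
        assert rep.texture_r["neg"] == pytest.approx(-1.0, abs=1e-12)
        assert rep.texture_selected == ["neg"]

    def test_constant_column_gets_zero(self, rng):
        y = rng.standard_normal(15)
        rep = correlation_select(pd.DataFrame({"const": np.ones(15)}), y)
        assert rep.texture_r["const"] == 0.0
        assert rep.texture_selected == []

    def test_matches_direct_pearson_formula(self, rng):
        y = rng.standard_normal(30)
        T = pd.DataFrame(rng.standard_normal((30, 6)), columns=list("abcdef"))
        rep = correlation_select(T, y)
        for col in T.columns:
            x = T[col].to_numpy()
            want = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
            )
            assert rep.texture_r[col] == pytest.approx(want, abs=1e-12)

    def test_planted_correlation_pattern(self, rng):
        """Rotation construction plants exact correlations: uniformity_PC2 the
        strongest negative, correlation_PC2 the strongest positive, seven
        features passing |r| > 0.3."""
        n = 200
        y = rng.standard_normal(n)
        yc = (y - y.mean()) / np.linalg.norm(y - y.mean())
        planted = {
            "correlation_PC1": 0.45, "contrast_PC1": -0.40, "entropy_PC1": 0.10,
            "uniformity_PC1": -0.35, "correlation_PC2": 0.58, "contrast_PC2": -0.45,
            "entropy_PC2": 0.05, "uniformity_PC2": -0.63, "correlation_PC3": 0.31,
            "contrast_PC3": 0.10, "entropy_PC3": -0.15, "uniformity_PC3": 0.20,
        }
        cols = {}
        for name, r in planted.items():
            e = rng.standard_normal(n)
            e -= e.mean()          # orthogonal to the ones vector (centred)
            e -= (e @ yc) * yc     # orthogonal to the response direction
            e /= np.linalg.norm(e)
            cols[name] = r * yc + np.sqrt(1 - r**2) * e
        T = pd.DataFrame(cols, columns=texture_feature_names())
        rep = correlation_select(T, y, threshold=0.3)
        for name, r in planted.items():
            assert rep.texture_r[name] == pytest.approx(r, abs=1e-10)
        assert rep.texture_r.idxmin() == "uniformity_PC2"
        assert rep.texture_r.idxmax() == "correlation_PC2"
        assert len(rep.texture_selected) == 7
        assert "entropy_PC2" not in rep.texture_selected


class TestFusion:
    def _blocks(self, rng, n=96):
        ids = [f"S{i:03d}" for i in range(n)]
        X = pd.DataFrame(rng.standard_normal((n, 428)), index=ids)
        T = pd.DataFrame(
            rng.standard_normal((n, 12)), index=ids, columns=texture_feature_names()
        )
        return X, T

    def test_low_level_concatenation_shape(self, rng):
        X, T = self._blocks(rng)
        fused = fuse_low(X, T)
        assert fused.shape == (96, 440)
        np.testing.assert_array_equal(fused.iloc[:, :428].to_numpy(), X.to_numpy())

    def test_empty_texture_block_returns_spectra(self, rng):
        X, T = self._blocks(rng, n=10)
        fused = fuse_low(X, T.iloc[:, :0])
        pd.testing.assert_frame_equal(fused, X)

    def test_row_mismatch_rejected(self, rng):
        X, T = self._blocks(rng, n=10)
        with pytest.raises(ValueError):
            fuse_low(X, T.iloc[:5])

    def test_mid_level_ten_plus_seven(self, rng):
        X, T = self._blocks(rng)
        cars = CARSResult(np.arange(10), np.arange(10.0), np.array([]), np.array([]), 0)
        sel = SelectionReport(pd.Series(0.5, index=T.columns[:7]), list(T.columns[:7]), 0.3)
        fused = fuse_mid(X, cars, T, sel)
        assert fused.shape == (96, 17)

    def test_full_selection_equals_low_level(self, rng):
        X, T = self._blocks(rng, n=20)
        cars = CARSResult(np.arange(428), np.array([]), np.array([]), np.array([]), 0)
        sel = SelectionReport(pd.Series(0.9, index=T.columns), list(T.columns), 0.3)
        pd.testing.assert_frame_equal(fuse_mid(X, cars, T, sel), fuse_low(X, T))

    def test_one_plus_one_order(self, rng):
        X, T = self._blocks(rng, n=10)
        cars = CARSResult(np.array([3]), np.array([400.0]), np.array([]), np.array([]), 0)
        sel = SelectionReport(pd.Series({"uniformity_PC2": -0.6}), ["uniformity_PC2"], 0.3)
        fused = fuse_mid(X, cars, T, sel)
        assert fused.shape == (10, 2)
        assert list(fused.columns)[1] == "uniformity_PC2"

    def test_empty_selections_rejected(self, rng):
        X, T = self._blocks(rng, n=10)
        cars = CARSResult(np.array([], dtype=int), np.array([]), np.array([]), np.array([]), 0)
        sel = SelectionReport(pd.Series(dtype=float), [], 0.3)
        with pytest.raises(ValueError):
            fuse_mid(X, cars, T, sel)
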