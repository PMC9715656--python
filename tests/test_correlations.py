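"""Pearson correlation maps, binned summaries, TWSA coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vegwater.correlations import (aridity_class, bin_by,
                                   iranwide_annual_correlation,
                                   pearson_r_p, pixelwise_met_correlation,
                                   twsa_vegetation_correlation)
from vegwater.hydromet import AnnualTwsa


class TestPearson:
    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(15), rng.random(15)
        r, p = pearson_r_p(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_self_correlation_is_one(self):
        x = np.random.default_rng(1).random(10)
        r, _ = pearson_r_p(x, x)
        assert r == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(12), rng.random(12)
        r0, _ = pearson_r_p(x, y)
        r1, _ = pearson_r_p(2.0 * x + 3.0, y)
        assert r1 == pytest.approx(r0)


class TestPixelwiseMet:
    def _annual(self, ny, nx, n, seed=0):
        return np.random.default_rng(seed).random((ny, nx, n))

    def test_affine_copy_gives_r_one_and_argmax(self):
        n = 10
        tp = self._annual(1, 1, n, seed=3)
        veg_pix = 0.1 + 0.5 * np.repeat(np.repeat(tp, 4, 0), 4, 1)
        met = {"tp": tp, "t2m": self._annual(1, 1, n, 4),
               "ai": self._annual(1, 1, n, 5)}
        maps = pixelwise_met_correlation(veg_pix, met, met_block=4)
        np.testing.assert_allclose(maps.r["tp"], 1.0)
        assert (maps.argmax_param == "tp").all()

    def test_r2max_dominates_each_parameter(self):
        met = {k: self._annual(2, 2, 12, i) for i, k in
               enumerate(("tp", "t2m", "ai"))}
        veg = self._annual(4, 4, 12, 9)
        maps = pixelwise_met_correlation(veg, met, met_block=2)
        for k in met:
            assert (maps.r2_max >= maps.r[k] ** 2 - 1e-12).all()

    def test_independent_noise_rejection_near_alpha(self):
        rng = np.random.default_rng(10)
        veg = rng.random((40, 40, 19))
        met = {"tp": rng.random((40, 40, 19))}
        maps = pixelwise_met_correlation(veg, met, met_block=1)
        rate = (maps.p["tp"] < 0.05).mean()
        assert 0.02 <= rate <= 0.09

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError, match="4 common years"):
            pixelwise_met_correlation(self._annual(2, 2, 3),
                                      {"tp": self._annual(2, 2, 3)}, 1)


class TestBinBy:
    def test_single_bin_global_median(self):
        vals = np.array([1.0, 2.0, 5.0])
        key = np.full(3, 10.0)
        out = bin_by(vals, key, binwidth=50.0)
        assert len(out) == 1
        assert out.iloc[0]["median"] == 2.0
        assert out.iloc[0].bin_left == 0.0

    def test_counts_conserved(self):
        rng = np.random.default_rng(3)
        vals, key = rng.random(500), rng.uniform(0, 400, 500)
        out = bin_by(vals, key, binwidth=50.0)
        assert out["count"].sum() == 500

    def test_monotone_binned_medians(self):
        """Values increasing with the key give monotone bin medians
        (the altitudinal-gradient pattern)."""
        rng = np.random.default_rng(4)
        key = rng.uniform(0, 1000, 2000)
        vals = 0.001 * key + rng.normal(0, 0.05, 2000)
        med = bin_by(vals, key, binwidth=200.0)["median"].to_numpy()
        assert (np.diff(med) > 0).all()

    def test_invalid_binwidth(self):
        with pytest.raises(ValueError):
            bin_by(np.ones(3), np.ones(3), binwidth=0.0)


class TestIranwide:
    def test_designed_couplings(self):
        rng = np.random.default_rng(5)
        n = 15
        tp = rng.random(n)
        veg = 0.2 + 0.5 * tp + rng.normal(0, 0.01, n)
        twsa = -np.arange(n, dtype=float) + rng.normal(0, 0.1, n)
        veg = veg + 0.01 * np.arange(n)          # increasing vegetation
        table, zs = iranwide_annual_correlation(
            {"veg": veg}, {"tp": tp, "t2m": rng.random(n)}, twsa)
        r = {row.parameter: row.r for row in table.itertuples()}
        assert r["tp"] > abs(r["t2m"])           # strongest for precipitation
        assert r["twsa"] < 0                     # greening despite TWS loss
        assert "veg" in zs and len(zs["veg"]) == n

    def test_excluded_years_dropped_pairwise(self):
        rng = np.random.default_rng(6)
        n = 12
        veg = rng.random(n)
        twsa = rng.random(n)
        twsa[[4, 5]] = np.nan
        table, _ = iranwide_annual_correlation({"veg": veg}, {}, twsa)
        assert table.iloc[0].n == 10

    def test_too_few_common_years(self):
        with pytest.raises(ValueError, match="fewer than 4"):
            iranwide_annual_correlation({"veg": np.ones(5) + np.arange(5)},
                                        {}, np.array([1, 2, np.nan, np.nan,
                                                      np.nan]))


class TestTwsaCorrelation:
    def _twsa(self, series):
        return AnnualTwsa(basin_ids=np.array([1]),
                          annual=np.asarray(series, dtype=float)[None, :],
                          years=np.arange(len(series)),
                          excluded_years=np.array([]))

    def test_pixel_equal_to_basin_series_r_one(self):
        n = 10
        series = np.random.default_rng(7).random(n)
        veg = np.tile(series, (2, 2, 1))
        out = twsa_vegetation_correlation(veg, self._twsa(series),
                                          np.ones((2, 2), int),
                                          np.ones((2, 2), bool))
        np.testing.assert_allclose(out["r_map"], 1.0)

    def test_share_counting_oracle(self):
        """20 of 100 pixels tracking TWSA -> share 20%."""
        rng = np.random.default_rng(8)
        n = 14
        base = rng.random(n)
        veg = rng.random((10, 10, n))            # uncorrelated noise
        veg.reshape(-1, n)[:20] = base + rng.normal(0, 0.01, (20, n))
        out = twsa_vegetation_correlation(veg, self._twsa(base),
                                          np.ones((10, 10), int),
                                          np.ones((10, 10), bool))
        share = out["basin_shares"].iloc[0].share_high_positive_pct
        assert share == pytest.approx(20.0, abs=4.0)

    def test_restricted_to_mask(self):
        n = 10
        series = np.random.default_rng(9).random(n)
        veg = np.tile(series, (2, 2, 1))
        mask = np.array([[True, False], [False, False]])
        out = twsa_vegetation_correlation(veg, self._twsa(series),
                                          np.ones((2, 2), int), mask)
        assert not np.isnan(out["r_map"][0, 0])
        assert np.isnan(out["r_map"][1, 1])

    def test_intensity_and_aridity_binning(self):
        n = 10
        series = np.random.default_rng(11).random(n)
        veg = np.tile(series, (4, 4, 1))
        intensity = np.linspace(0, 100, 16).reshape(4, 4)
        aridity = np.full((4, 4), 0.1)
        out = twsa_vegetation_correlation(
            veg, self._twsa(series), np.ones((4, 4), int),
            np.ones((4, 4), bool), intensity=intensity, aridity=aridity)
        assert isinstance(out["r_by_intensity"], pd.DataFrame)
        arid_tab = out["r_by_aridity"]
        row = arid_tab[arid_tab.aridity_class == "arid"].iloc[0]
        assert row["count"] > 0


def test_aridity_class_breaks():
    labels = aridity_class(np.array([0.01, 0.1, 0.3, 0.6, 0.9]))
    assert list(labels) == ["hyper-arid", "arid", "semi-arid",
                            "dry sub-humid", "humid"]
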