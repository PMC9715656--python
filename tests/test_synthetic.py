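"""Scene generator: ground-truth contracts and reproducibility."""

import numpy as np
import pytest
from scipy.signal import argrelmax

from vegwater import GeneratorConfig
from vegwater.config import COMPOSITES_PER_YEAR, default_class_params
from vegwater.resample import block_average
from vegwater.synthetic import (generate_ancillary, generate_met_series,
                                generate_ndvi_cube, generate_scene)


def test_seed_is_required():
    with pytest.raises(ValueError, match="seed"):
        GeneratorConfig(seed=None)


def test_invalid_dimensions_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(seed=1, grid_size=1)
    with pytest.raises(ValueError):
        GeneratorConfig(seed=1, n_years=2)
    with pytest.raises(ValueError):
        GeneratorConfig(seed=1, outlier_rate=0.6)


def test_zero_noise_cube_equals_clean_curves(clean_cube):
    """Without noise/outliers/snow the cube is exactly the class curves."""
    cube, truth = clean_cube
    np.testing.assert_array_equal(cube.ndvi, truth.clean_ndvi)
    assert not cube.qa_snow.any()
    assert (cube.qa_quality == 0).all()


def test_outlier_flag_fraction_matches_binomial():
    """Degraded-QA fraction ~ outlier_rate * flagged_fraction (binomial)."""
    cfg = GeneratorConfig(seed=7, grid_size=16, n_years=4, outlier_rate=0.1,
                          snow_max_composites=0)
    cube, _ = generate_ndvi_cube(cfg)
    n = cube.ndvi.size
    expected = 0.1 * cfg.outlier_flagged_fraction
    observed = (cube.qa_quality > 2).mean()
    # 5-sigma binomial band
    tol = 5 * np.sqrt(expected * (1 - expected) / n)
    assert abs(observed - expected) < tol


def test_crop_double_has_two_seasonal_peaks():
    params = default_class_params(5)["crop_double"]
    curve = params.seasonal_curve(np.arange(COMPOSITES_PER_YEAR, dtype=float))
    peaks = argrelmax(curve)[0]
    assert len(peaks) == 2


def test_regeneration_is_bit_identical_and_seed_sensitive():
    a = generate_scene(GeneratorConfig(seed=5, grid_size=8, n_years=4))
    b = generate_scene(GeneratorConfig(seed=5, grid_size=8, n_years=4))
    c = generate_scene(GeneratorConfig(seed=6, grid_size=8, n_years=4))
    np.testing.assert_array_equal(a.cube.ndvi, b.cube.ndvi)
    np.testing.assert_array_equal(a.ancillary.twsa.monthly,
                                  b.ancillary.twsa.monthly)
    assert not np.array_equal(a.cube.ndvi, c.cube.ndvi)


def test_class_conditional_mean_ordering(clean_cube):
    """Noiseless annual means order crop_double > crop_single >
    natural_sparse > bare."""
    cube, truth = clean_cube
    means = {}
    for name in ("crop_double", "crop_single", "natural_sparse", "bare"):
        sel = truth.pixel_class == name
        if sel.any():
            means[name] = cube.ndvi[sel].mean()
    keys = [k for k in ("crop_double", "crop_single", "natural_sparse",
                        "bare") if k in means]
    vals = [means[k] for k in keys]
    assert all(vals[i] > vals[i + 1] for i in range(len(vals) - 1))


def test_outliers_only_lower_ndvi(small_scene):
    """Cloud-like contamination only decreases NDVI values."""
    cfg = small_scene.config
    clean_plus_noise = GeneratorConfig(
        seed=cfg.seed, grid_size=cfg.grid_size, n_years=cfg.n_years,
        outlier_rate=0.0)
    ref, _ = generate_ndvi_cube(clean_plus_noise)
    flagged = small_scene.cube.qa_quality > 2
    assert (small_scene.cube.ndvi[flagged] <= ref.ndvi[flagged] + 1e-12).all()


def test_snow_composites_within_range(small_scene):
    counts = small_scene.truth.snow_composites
    assert counts.min() >= 0 and counts.max() <= COMPOSITES_PER_YEAR
    # qa_snow flags agree with the per-year counts
    per_year = small_scene.cube.qa_snow.reshape(
        *counts.shape[:2], counts.shape[2], COMPOSITES_PER_YEAR).sum(axis=-1)
    np.testing.assert_array_equal(per_year, counts)


def test_crop_fraction_separates_crop_pixels(small_scene):
    crop_frac = block_average(small_scene.ancillary.crop_frac_fine,
                              small_scene.config.crop_fine_factor)
    is_crop = np.char.startswith(
        small_scene.truth.pixel_class.astype(str), "crop")
    assert (crop_frac[is_crop] > 20).all()
    assert (crop_frac[~is_crop] < 20).all()


def test_twsa_trend_without_noise_strictly_decreasing():
    cfg = GeneratorConfig(seed=3, grid_size=8, n_years=4, twsa_noise_mm=0.0,
                          twsa_seasonal_mm=0.0, twsa_gap_months=[])
    scene = generate_scene(cfg)
    annual = scene.ancillary.twsa.monthly.reshape(-1, 4, 12).mean(axis=-1)
    assert (np.diff(annual, axis=1) < 0).all()


def test_met_series_contracts():
    cfg = GeneratorConfig(seed=11, grid_size=16, n_years=8)
    met = generate_met_series(cfg)
    assert (met.tp >= 0).all()
    assert (met.pev < 0).all()      # reanalysis sign convention
    # warming trend recovered by OLS on country-mean annual t2m
    ann = met.t2m.mean(axis=(0, 1)).reshape(8, 12).mean(axis=1)
    slope = np.polyfit(np.arange(8), ann, 1)[0]
    assert abs(slope - cfg.warming_trend) < 0.1


def test_met_zero_variability_gives_identical_years():
    cfg = GeneratorConfig(seed=2, grid_size=8, n_years=4, warming_trend=0.0,
                          tp_interannual_sd=0.0, t2m_noise_sd=0.0)
    # remove cell-level interannual noise by averaging check on tp only
    met = generate_met_series(cfg)
    tp_ann = met.tp.reshape(*met.tp.shape[:2], 4, 12).sum(axis=-1)
    sd = tp_ann.std(axis=-1) / tp_ann.mean(axis=-1)
    assert sd.max() < 0.2  # only residual cell noise remains


def test_scripted_lc_transitions_recorded(small_scene):
    truth = small_scene.truth
    lc = small_scene.ancillary.landcover
    names = list(lc.class_names)
    for row in truth.lc_flips.itertuples():
        prev, cur = lc.maps[row.year_index - 1], lc.maps[row.year_index]
        f, t = names.index(row.from_class), names.index(row.to_class)
        n = ((prev == f) & (cur == t)).sum()
        assert n >= row.n_pixels  # scripted flips present (other flips may add)


def test_ancillary_grid_mismatch_rejected(small_scene):
    cfg = GeneratorConfig(seed=9, grid_size=8, n_years=4)
    with pytest.raises(ValueError, match="mismatch"):
        generate_ancillary(small_scene.truth, cfg)
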