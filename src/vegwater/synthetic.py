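"""Synthetic scene generator with known ground truth.

Emulates the statistical structure of the real inputs of the analysis --
16-day NDVI composites with quality flags, snow flags, monthly meteorology
on a coarser grid, a fine cropland-fraction raster, annual categorical
land-cover maps, basin total-water-storage-anomaly series and a DEM -- so
that every downstream stage can be tested against a scene whose phenology
class, trend magnitude, irrigation status, snow period and land-cover
transitions are known exactly.

Everything is driven by a single integer seed through named
``numpy.random.SeedSequence`` child streams, so regeneration is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import (
    COMPOSITES_PER_YEAR,
    MONTHS_PER_YEAR,
    GeneratorConfig,
    PIXEL_CLASSES,
    composite_month_index,
)

LC_CLASSES = (
    "crops",
    "trees",
    "shrubs/sparse vegetation/grassland",
    "inundated",
    "urban",
    "bare",
    "water",
)

# fixed winter-peaked monthly precipitation weights (Oct..Sep); the six
# colder months Nov-Apr carry ~75% of the annual total
_TP_MONTH_WEIGHTS = np.array(
    [0.05, 0.09, 0.13, 0.16, 0.15, 0.13, 0.10, 0.06, 0.04, 0.02, 0.03, 0.04]
)
# summer-peaked potential-evaporation weights (Oct..Sep)
_PEV_MONTH_WEIGHTS = np.array(
    [0.05, 0.04, 0.03, 0.03, 0.04, 0.06, 0.08, 0.11, 0.13, 0.15, 0.15, 0.13]
)

_STREAMS = ("met", "classes", "noise", "ancillary", "twsa", "landcover")


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


@dataclass
class NDVICube:
    """16-day NDVI composites with per-composite quality flags.

    ``ndvi`` has shape (ny, nx, n_years * 23); ``qa_quality`` is the
    VIQuality-like integer code (0 good .. 3 degraded) and ``qa_snow`` the
    possible-snow/ice flag.
    """

    ndvi: np.ndarray
    qa_quality: np.ndarray
    qa_snow: np.ndarray
    years: np.ndarray
    mask: Optional[np.ndarray] = None

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def shape(self) -> tuple:
        return self.ndvi.shape


@dataclass
class MetSeries:
    """Monthly meteorology on the coarse grid (one cell per met_block^2 pixels)."""

    tp: np.ndarray    # (ncy, ncx, n_years*12) mm per month, >= 0
    t2m: np.ndarray   # K
    pev: np.ndarray   # mm per month, negative by convention
    years: np.ndarray
    met_block: int

    @property
    def n_years(self) -> int:
        return len(self.years)


@dataclass
class TwsaSeries:
    """Monthly basin-aggregated total water storage anomalies (mm)."""

    basin_ids: np.ndarray        # (n_basins,)
    monthly: np.ndarray          # (n_basins, n_years*12), NaN at gap months
    years: np.ndarray
    gap_months: np.ndarray       # indices of missing months

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b, bid in enumerate(self.basin_ids):
            for m in range(self.monthly.shape[1]):
                wy = self.years[m // MONTHS_PER_YEAR]
                rows.append((int(bid), int(wy), m % MONTHS_PER_YEAR,
                             self.monthly[b, m]))
        return pd.DataFrame(rows, columns=["basin_id", "water_year",
                                           "month_of_wy", "twsa_mm"])


@dataclass
class LandCoverSeries:
    """Annual categorical land-cover maps over the 7 compound classes."""

    maps: np.ndarray             # (n_years, ny, nx) int codes into class_names
    class_names: tuple
    years: np.ndarray
    pixel_area_km2: float = 0.0625   # 250 m pixels


@dataclass
class Ancillary:
    crop_frac_fine: np.ndarray   # (ny*f, nx*f) percent
    snow_flags: np.ndarray       # (ny, nx, T) bool, per composite
    landcover: LandCoverSeries
    twsa: TwsaSeries
    dem: np.ndarray              # (ny, nx) metres


@dataclass
class SceneTruth:
    """Ground truth of the generated scene."""

    pixel_class: np.ndarray          # (ny, nx) of PIXEL_CLASSES strings
    true_trend: np.ndarray           # (ny, nx) annual-mean NDVI units / year
    irrigated: np.ndarray            # (ny, nx) bool
    snow_composites: np.ndarray      # (ny, nx, n_years) int counts
    basin_id: np.ndarray             # (ny, nx) int
    clean_ndvi: np.ndarray           # noiseless, outlier/snow-free cube
    newly_cultivated: np.ndarray     # (ny, nx) bool, scripted bare->crop pixels
    conversion_year_index: int
    elevation: np.ndarray            # (ny, nx) metres
    tp_anomaly: np.ndarray           # (n_years,) shared wet/dry z anomaly
    cell_ai: np.ndarray              # (ncy, ncx) long-term aridity index
    lc_flips: pd.DataFrame = field(default_factory=pd.DataFrame)
    # per scripted year: columns year_index, from_class, to_class, n_pixels


@dataclass
class Scene:
    """Full bundle of generated inputs plus truth."""

    cube: NDVICube
    truth: SceneTruth
    met: MetSeries
    ancillary: Ancillary
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# internal deterministic building blocks
# ---------------------------------------------------------------------------

def _elevation(config: GeneratorConfig) -> np.ndarray:
    n = config.grid_size
    y = np.arange(n)[:, None] / max(n - 1, 1)
    x = np.arange(n)[None, :] / max(n - 1, 1)
    # high north (row 0), sloping to low south, with a gentle east-west ripple
    return config.dem_max_m * (1.0 - y) * (0.9 + 0.1 * np.cos(2 * np.pi * x))


def _met_fields(config: GeneratorConfig):
    """Annual-scale met climatology per coarse cell and shared anomalies."""
    rng = _rng(config, "met")
    nc = config.grid_size // config.met_block
    x = np.arange(nc)[None, :] / max(nc - 1, 1)
    x = np.broadcast_to(x, (nc, nc)).copy()
    tp_annual = config.tp_west_mm + (config.tp_east_mm - config.tp_west_mm) * x
    pev_annual = config.pev_west_mm + (config.pev_east_mm - config.pev_west_mm) * x
    # shared country-wide wet/dry anomaly per water year
    z = rng.standard_normal(config.n_years)
    cell_noise = rng.normal(0.0, 0.05, size=(nc, nc, config.n_years))
    t2m_noise = rng.normal(0.0, config.t2m_noise_sd,
                           size=(nc, nc, config.n_years * MONTHS_PER_YEAR))
    return tp_annual, pev_annual, z, cell_noise, t2m_noise


def _pixel_classes(config: GeneratorConfig, cell_ai: np.ndarray):
    """Aridity-stratified random class assignment plus scripted conversions."""
    rng = _rng(config, "classes")
    n = config.grid_size
    ai_pix = np.repeat(np.repeat(cell_ai, config.met_block, axis=0),
                       config.met_block, axis=1)
    # class probabilities by aridity stratum (order = PIXEL_CLASSES)
    strata = [
        (0.50, np.array([0.05, 0.20, 0.35, 0.20, 0.10, 0.02, 0.08])),
        (0.20, np.array([0.15, 0.30, 0.15, 0.15, 0.08, 0.07, 0.10])),
        (0.05, np.array([0.40, 0.20, 0.03, 0.12, 0.08, 0.07, 0.10])),
        (-1.0, np.array([0.60, 0.10, 0.00, 0.10, 0.07, 0.06, 0.07])),
    ]
    u = rng.random((n, n))
    codes = np.zeros((n, n), dtype=int)
    for lo, probs in strata:
        sel = ai_pix >= lo if lo >= 0 else np.ones_like(ai_pix, bool)
        sel &= codes == 0
        cum = np.cumsum(probs)
        idx = np.searchsorted(cum, u, side="right").clip(0, 6)
        codes = np.where(sel & (codes == 0), idx + 1, codes)
    codes -= 1
    classes = np.array(PIXEL_CLASSES, dtype=object)[codes]

    # scripted bare -> cropland conversions mid-period
    bare_idx = np.flatnonzero((classes == "bare").ravel())
    n_conv = int(round(config.conversion_fraction * bare_idx.size))
    conv = rng.choice(bare_idx, size=n_conv, replace=False) if n_conv else []
    newly = np.zeros((n, n), dtype=bool)
    newly.ravel()[conv] = True
    classes[newly] = "crop_single"
    return classes, newly, ai_pix


def _basins(config: GeneratorConfig) -> np.ndarray:
    """Quadrant-block basins, ids 1..n_basins."""
    n = config.grid_size
    k = int(np.ceil(np.sqrt(config.n_basins)))
    yb = np.minimum(np.arange(n) * k // n, k - 1)
    xb = np.minimum(np.arange(n) * k // n, k - 1)
    ids = yb[:, None] * k + xb[None, :] + 1
    return np.minimum(ids, config.n_basins)


def _snow_counts(config: GeneratorConfig, elevation: np.ndarray) -> np.ndarray:
    rng = _rng(config, "ancillary")
    n = config.grid_size
    if config.snow_max_composites <= 0:
        return np.zeros((n, n, config.n_years), dtype=int)
    frac = np.clip((elevation - config.snow_elev_threshold_m)
                   / max(config.dem_max_m - config.snow_elev_threshold_m, 1.0),
                   0.0, 1.0)
    base = np.rint(config.snow_max_composites * frac).astype(int)
    jitter = rng.integers(-1, 2, size=(n, n, config.n_years))
    counts = np.clip(base[:, :, None] + jitter, 0, COMPOSITES_PER_YEAR)
    counts[base == 0] = 0
    return counts


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def generate_met_series(config: GeneratorConfig) -> MetSeries:
    """Monthly tp / t2m / pev on the coarse met grid.

    Precipitation is winter-peaked (roughly three quarters of the annual
    total falls November-April) and declines from the western to the
    eastern edge of the scene; potential evaporation is summer-peaked,
    reported negative following the reanalysis sign convention; air
    temperature carries the configured warming trend.
    """
    tp_annual, pev_annual, z, cell_noise, t2m_noise = _met_fields(config)
    nc = tp_annual.shape[0]
    ny_t = config.n_years
    mult = np.clip(1.0 + config.tp_interannual_sd * z[None, None, :]
                   + cell_noise, 0.1, None)          # (nc, nc, n_years)
    tp = (tp_annual[:, :, None, None] * mult[:, :, :, None]
          * _TP_MONTH_WEIGHTS[None, None, None, :])
    tp = tp.reshape(nc, nc, ny_t * MONTHS_PER_YEAR)
    pev_mag = (pev_annual[:, :, None, None]
               * np.ones((1, 1, ny_t, 1))
               * _PEV_MONTH_WEIGHTS[None, None, None, :])
    pev = -pev_mag.reshape(nc, nc, ny_t * MONTHS_PER_YEAR)

    month = np.arange(ny_t * MONTHS_PER_YEAR)
    season = -10.0 * np.cos(2 * np.pi * (month % 12 - 9) / 12.0)  # peak in July
    elev = _elevation(config)
    cell_elev = elev.reshape(nc, config.met_block, nc, config.met_block)
    cell_elev = cell_elev.mean(axis=(1, 3))
    t2m = (config.t2m_base_k
           - 0.0065 * cell_elev[:, :, None]
           + season[None, None, :]
           + config.warming_trend * (month[None, None, :] / 12.0)
           + t2m_noise)
    return MetSeries(tp=tp, t2m=t2m, pev=pev, years=config.years,
                     met_block=config.met_block)


def _long_term_cell_ai(met: MetSeries) -> np.ndarray:
    ny_t = met.n_years
    tp_a = met.tp.reshape(*met.tp.shape[:2], ny_t, MONTHS_PER_YEAR).sum(axis=3)
    pev_a = np.abs(met.pev).reshape(*met.pev.shape[:2], ny_t,
                                    MONTHS_PER_YEAR).sum(axis=3)
    return (tp_a / pev_a).mean(axis=2)


def generate_ndvi_cube(config: GeneratorConfig) -> tuple[NDVICube, SceneTruth]:
    """The synthetic 16-day NDVI cube plus its ground truth.

    Per pixel the noiseless signal is the class seasonal curve (sum of
    double-logistic pulses) with: a linear inter-annual drift equal to the
    class trend, amplitude coupling to the shared wet/dry anomaly for
    rain-sensitive classes, a persistent amplitude drop after the break
    year for abandoned cropland, and a bare->crop switch at the conversion
    year for scripted newly-cultivated pixels.  Contamination: additive
    Gaussian noise, negative-biased outliers (value multiplied by
    U(0.1, 0.6)) flagged degraded in 90% of cases, and snow composites set
    to ``snow_ndvi`` with the snow flag raised.
    """
    met = generate_met_series(config)
    cell_ai = _long_term_cell_ai(met)
    classes, newly, ai_pix = _pixel_classes(config, cell_ai)
    elevation = _elevation(config)
    snow_counts = _snow_counts(config, elevation)
    basins = _basins(config)

    n = config.grid_size
    ny_t = config.n_years
    T = ny_t * COMPOSITES_PER_YEAR
    t_comp = np.arange(COMPOSITES_PER_YEAR, dtype=float)

    # recover the shared anomaly (identical stream as generate_met_series)
    _, _, z_anom, _, _ = _met_fields(config)

    params = config.class_params
    assert params is not None

    # per-class template curves (seasonal only)
    irrigated = np.isin(classes, ["crop_double", "crop_abandoned",
                                  "crop_intensifying"])
    irrigated |= (classes == "crop_single") & (
        ai_pix < config.crop_irrigation_ai_threshold)

    # irrigated single-cycle crops grow in the dry summer instead of spring
    summer_single = params["crop_intensifying"].seasonal_curve(t_comp)
    curves = {}
    for name in PIXEL_CLASSES:
        curves[name] = params[name].seasonal_curve(t_comp)

    clean = np.zeros((n, n, T))
    true_trend = np.zeros((n, n))
    for name in PIXEL_CLASSES:
        sel = classes == name
        if not sel.any():
            continue
        p = params[name]
        true_trend[sel] = p.trend
        base_curve = curves[name]
        for iy in range(ny_t):
            amp_factor = 1.0 + p.met_coupling * z_anom[iy]
            # amplitude coupling acts on the pulse part only
            seasonal = p.base + (base_curve - p.base) * max(amp_factor, 0.1)
            if p.break_year is not None and iy >= p.break_year:
                seasonal = p.base + (base_curve - p.base) * p.break_factor
            yearly = seasonal + p.trend * iy
            sl = slice(iy * COMPOSITES_PER_YEAR, (iy + 1) * COMPOSITES_PER_YEAR)
            clean[sel, sl] = yearly[None, :]

    # irrigated crop_single pixels: replace spring pulse by the summer pulse
    sel = (classes == "crop_single") & irrigated
    if sel.any():
        p = params["crop_single"]
        for iy in range(ny_t):
            yearly = summer_single
            sl = slice(iy * COMPOSITES_PER_YEAR, (iy + 1) * COMPOSITES_PER_YEAR)
            clean[sel, sl] = yearly[None, :]

    # scripted conversions: bare curve before the conversion year
    if newly.any():
        bare_curve = curves["bare"]
        for iy in range(config.conversion_year_index):
            sl = slice(iy * COMPOSITES_PER_YEAR, (iy + 1) * COMPOSITES_PER_YEAR)
            clean[newly, sl] = bare_curve[None, :]

    clean = np.clip(clean, -0.2, 1.0)

    rng = _rng(config, "noise")
    ndvi = clean.copy()
    if config.annual_noise_sd > 0:
        ann = rng.normal(0.0, config.annual_noise_sd, size=(n, n, ny_t))
        ndvi = ndvi + np.repeat(ann, COMPOSITES_PER_YEAR, axis=2)
    if config.noise_sd > 0:
        ndvi = ndvi + rng.normal(0.0, config.noise_sd, size=ndvi.shape)

    qa_quality = np.zeros(ndvi.shape, dtype=np.int8)
    if config.outlier_rate > 0:
        is_outlier = rng.random(ndvi.shape) < config.outlier_rate
        factor = rng.uniform(0.1, 0.6, size=ndvi.shape)
        # outliers only ever lower NDVI (cloud model), also at negative values
        ndvi = np.where(is_outlier, np.minimum(ndvi, ndvi * factor), ndvi)
        flagged = is_outlier & (rng.random(ndvi.shape)
                                < config.outlier_flagged_fraction)
        qa_quality[flagged] = 3

    # snow composites: winter positions, value forced to snow_ndvi
    qa_snow = np.zeros(ndvi.shape, dtype=bool)
    if snow_counts.any():
        winter_start = 4  # composite index of early December
        pos = np.arange(COMPOSITES_PER_YEAR)
        for iy in range(ny_t):
            cnt = snow_counts[:, :, iy]
            within = (pos[None, None, :] >= winter_start) & \
                     (pos[None, None, :] < winter_start + cnt[:, :, None])
            sl = slice(iy * COMPOSITES_PER_YEAR, (iy + 1) * COMPOSITES_PER_YEAR)
            qa_snow[:, :, sl] = within
        ndvi = np.where(qa_snow, config.snow_ndvi, ndvi)

    ndvi = np.clip(ndvi, -0.2, 1.0)

    cube = NDVICube(ndvi=ndvi, qa_quality=qa_quality, qa_snow=qa_snow,
                    years=config.years)
    truth = SceneTruth(
        pixel_class=classes,
        true_trend=true_trend,
        irrigated=irrigated,
        snow_composites=snow_counts,
        basin_id=basins,
        clean_ndvi=clean,
        newly_cultivated=newly,
        conversion_year_index=config.conversion_year_index,
        elevation=elevation,
        tp_anomaly=z_anom,
        cell_ai=cell_ai,
    )
    return cube, truth


def generate_ancillary(truth: SceneTruth, config: GeneratorConfig) -> Ancillary:
    """Crop-fraction raster, snow flags, land-cover series, TWSA and DEM."""
    if truth.pixel_class.shape != (config.grid_size, config.grid_size):
        raise ValueError("truth/grid mismatch")
    # independent child of the ancillary stream (_snow_counts uses the parent)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(len(_STREAMS))[3].spawn(2)[1])

    n = config.grid_size
    f = config.crop_fine_factor
    is_crop = np.char.startswith(truth.pixel_class.astype(str), "crop")
    fine = rng.uniform(0.0, 12.0, size=(n * f, n * f))
    crop_fine = rng.uniform(45.0, 90.0, size=(n * f, n * f))
    crop_mask_fine = np.repeat(np.repeat(is_crop, f, axis=0), f, axis=1)
    crop_frac_fine = np.where(crop_mask_fine, crop_fine, fine)

    snow_flags = _snow_flags_from_counts(truth.snow_composites)
    landcover = _generate_landcover(truth, config)
    twsa = _generate_twsa(truth, config)
    dem = truth.elevation.copy()
    return Ancillary(crop_frac_fine=crop_frac_fine, snow_flags=snow_flags,
                     landcover=landcover, twsa=twsa, dem=dem)


def _snow_flags_from_counts(snow_counts: np.ndarray) -> np.ndarray:
    ny, nx, n_years = snow_counts.shape
    flags = np.zeros((ny, nx, n_years * COMPOSITES_PER_YEAR), dtype=bool)
    pos = np.arange(COMPOSITES_PER_YEAR)
    winter_start = 4
    for iy in range(n_years):
        cnt = snow_counts[:, :, iy]
        within = (pos[None, None, :] >= winter_start) & \
                 (pos[None, None, :] < winter_start + cnt[:, :, None])
        sl = slice(iy * COMPOSITES_PER_YEAR, (iy + 1) * COMPOSITES_PER_YEAR)
        flags[:, :, sl] = within
    return flags


_BASE_LC = {
    "bare": "bare",
    "natural_sparse": "shrubs/sparse vegetation/grassland",
    "natural_dense": "trees",
    "crop_single": "crops",
    "crop_double": "crops",
    "crop_abandoned": "crops",
    "crop_intensifying": "crops",
}


def _generate_landcover(truth: SceneTruth, config: GeneratorConfig
                        ) -> LandCoverSeries:
    """Annual 7-class maps with scripted, anomaly-coupled sparse<->bare flips.

    Dry years (negative shared precipitation anomaly) flip sparse-vegetation
    pixels to bare ground, wet years flip bare pixels back; scripted
    bare->crops conversions appear at the conversion year.  All flips
    persist until reversed, and every scripted flip is recorded in
    ``truth.lc_flips`` so change accounting can be checked exactly.
    """
    rng = _rng(config, "landcover")
    n = config.grid_size
    code = {name: i for i, name in enumerate(LC_CLASSES)}
    base = np.vectorize(lambda c: code[_BASE_LC[str(c)]])(truth.pixel_class)
    # newly cultivated pixels start as bare in the land-cover series too
    base = base.astype(int)
    base[truth.newly_cultivated] = code["bare"]

    # small static water / urban / inundated patches so all classes occur
    base[0:3, 0:3] = code["water"]
    base[0:4, n - 4:n] = code["urban"]
    base[n - 1, 0:8] = code["inundated"]

    maps = np.empty((config.n_years, n, n), dtype=int)
    current = base.copy()
    flips = []
    sparse_code, bare_code = code["shrubs/sparse vegetation/grassland"], code["bare"]
    for iy in range(config.n_years):
        if iy > 0:
            z = truth.tp_anomaly[iy]
            k = int(round(config.lc_flip_scale * abs(z)))
            if z < 0 and k > 0:
                pool = np.flatnonzero((current == sparse_code).ravel())
                pick = rng.choice(pool, size=min(k, pool.size), replace=False)
                current.ravel()[pick] = bare_code
                flips.append((iy, "shrubs/sparse vegetation/grassland",
                              "bare", len(pick)))
            elif z > 0 and k > 0:
                pool = np.flatnonzero((current == bare_code).ravel()
                                      & ~truth.newly_cultivated.ravel())
                pick = rng.choice(pool, size=min(k, pool.size), replace=False)
                current.ravel()[pick] = sparse_code
                flips.append((iy, "bare",
                              "shrubs/sparse vegetation/grassland", len(pick)))
            if iy == truth.conversion_year_index and truth.newly_cultivated.any():
                current[truth.newly_cultivated] = code["crops"]
                flips.append((iy, "bare", "crops",
                              int(truth.newly_cultivated.sum())))
        maps[iy] = current
    truth.lc_flips = pd.DataFrame(
        flips, columns=["year_index", "from_class", "to_class", "n_pixels"])
    return LandCoverSeries(maps=maps, class_names=LC_CLASSES,
                           years=config.years)


def _default_gap_months(config: GeneratorConfig) -> np.ndarray:
    """11-month inter-mission block (July of year N-2 .. May of year N-1) plus
    two isolated single-month outages earlier in the series."""
    T = config.n_years * MONTHS_PER_YEAR
    if 2017 in config.years and 2018 in config.years:
        start = (2017 - config.first_year) * MONTHS_PER_YEAR + 9  # July
    else:
        start = max(T - 27, MONTHS_PER_YEAR)
    block = np.arange(start, min(start + 11, T))
    singles = np.array([int(0.35 * T), int(0.55 * T)])
    return np.unique(np.concatenate([singles, block]))


def _generate_twsa(truth: SceneTruth, config: GeneratorConfig) -> TwsaSeries:
    rng = _rng(config, "twsa")
    T = config.n_years * MONTHS_PER_YEAR
    t = np.arange(T)
    basin_ids = np.unique(truth.basin_id)
    series = np.empty((basin_ids.size, T))
    for b in range(basin_ids.size):
        scale = 1.0 + 0.3 * rng.standard_normal()
        season = config.twsa_seasonal_mm * np.cos(2 * np.pi * (t % 12 - 6) / 12)
        trend = config.twsa_trend_mm * scale * t / 12.0
        noise = rng.normal(0.0, config.twsa_noise_mm, size=T)
        s = trend + season + noise
        series[b] = s - s.mean()
    gaps = (np.asarray(config.twsa_gap_months, dtype=int)
            if config.twsa_gap_months is not None
            else _default_gap_months(config))
    gaps = gaps[(gaps >= 0) & (gaps < T)]
    series[:, gaps] = np.nan
    return TwsaSeries(basin_ids=basin_ids, monthly=series,
                      years=config.years, gap_months=gaps)


def generate_scene(config: GeneratorConfig) -> Scene:
    """Generate the full input bundle (cube, truth, met, ancillary)."""
    cube, truth = generate_ndvi_cube(config)
    met = generate_met_series(config)
    anc = generate_ancillary(truth, config)
    return Scene(cube=cube, truth=truth, met=met, ancillary=anc, config=config)
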