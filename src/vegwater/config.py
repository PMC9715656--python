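"""Configuration objects and the water-year calendar shared across the pipeline.

The temporal backbone of the analysis is the hydrological *water year*
running from October 1 to September 30 and labelled by the calendar year of
its September end (Oct 2000 - Sep 2001 -> label 2001).  Vegetation is
observed as 23 sixteen-day NDVI composites per water year; meteorology is
monthly (12 months per water year, October first).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

COMPOSITES_PER_YEAR = 23
MONTHS_PER_YEAR = 12

# Month lengths of a nominal (non-leap) water year, October .. September.
_WY_MONTH_LENGTHS = np.array([31, 30, 31, 31, 28, 31, 30, 31, 30, 31, 31, 30])
_WY_MONTH_STARTS = np.concatenate([[0], np.cumsum(_WY_MONTH_LENGTHS)[:-1]])


def composite_start_days() -> np.ndarray:
    """Start day (within the water year, 0 = Oct 1) of each 16-day composite."""
    return np.arange(COMPOSITES_PER_YEAR) * 16


def composite_month_index() -> np.ndarray:
    """Water-year month index (0 = October .. 11 = September) of each composite.

    A composite is assigned to the month containing its start date; every
    month receives at least one composite.
    """
    days = composite_start_days()
    return np.searchsorted(_WY_MONTH_STARTS, days, side="right") - 1


@dataclass
class PulseParams:
    """One double-logistic greenness pulse within the water year.

    ``onset``/``offset`` are in composite index units (0..22); ``rate``
    controls the steepness of the logistic flanks.
    """

    amplitude: float
    onset: float
    offset: float
    rate: float = 0.8

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        up = 1.0 / (1.0 + np.exp(-(t - self.onset) / self.rate))
        down = 1.0 / (1.0 + np.exp((t - self.offset) / self.rate))
        return self.amplitude * up * down


@dataclass
class ClassParams:
    """Ground-truth phenology of one pixel class.

    ``met_coupling`` scales pulse amplitudes with the annual precipitation
    anomaly (natural vegetation responds to wet/dry years, irrigated crops
    do not).  ``trend`` is the injected inter-annual drift in annual-mean
    NDVI units per year.  ``break_year``/``break_factor`` implement
    abandonment as a persistent amplitude drop after the break.
    """

    base: float
    pulses: list[PulseParams] = field(default_factory=list)
    trend: float = 0.0
    met_coupling: float = 0.0
    break_year: Optional[int] = None
    break_factor: float = 1.0

    def seasonal_curve(self, t: np.ndarray) -> np.ndarray:
        out = np.full_like(t, self.base, dtype=float)
        for p in self.pulses:
            out = out + p.evaluate(t)
        return out


PIXEL_CLASSES = (
    "bare",
    "natural_sparse",
    "natural_dense",
    "crop_single",
    "crop_double",
    "crop_abandoned",
    "crop_intensifying",
)


def default_class_params(n_years: int) -> dict[str, ClassParams]:
    """Phenology parameters of the seven synthetic pixel classes.

    Timing is expressed in composite index within the water year
    (composite ~9.5 = March, ~15.5 = June).  Rainfed growth peaks in the
    wet spring; irrigated growth peaks in the dry summer, which is what the
    irrigation-probability scoring keys on.
    """
    return {
        "bare": ClassParams(base=0.05),
        "natural_sparse": ClassParams(
            base=0.08,
            pulses=[PulseParams(0.18, 9.5, 14.5, 0.8)],
            trend=-0.005,
            met_coupling=0.15,
        ),
        "natural_dense": ClassParams(
            base=0.15,
            pulses=[PulseParams(0.45, 8.5, 17.0, 1.0)],
            trend=0.005,
            met_coupling=0.05,
        ),
        # rainfed single-cycle cropping in spring; the generator switches the
        # pulse to summer for pixels flagged irrigated
        "crop_single": ClassParams(
            base=0.12,
            pulses=[PulseParams(0.45, 9.5, 14.0, 0.7)],
            met_coupling=0.10,
        ),
        "crop_double": ClassParams(
            base=0.12,
            pulses=[
                PulseParams(0.50, 9.0, 13.0, 0.6),
                PulseParams(0.55, 15.5, 19.5, 0.6),
            ],
        ),
        "crop_abandoned": ClassParams(
            base=0.12,
            pulses=[PulseParams(0.50, 15.5, 20.0, 0.7)],
            break_year=max(n_years // 2, 1),
            break_factor=0.25,
        ),
        "crop_intensifying": ClassParams(
            base=0.12,
            pulses=[PulseParams(0.50, 15.5, 20.0, 0.7)],
            trend=0.005,
        ),
    }


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic scene generator.

    The defaults define the reference scene: a 64 x 64 pixel grid observed
    over the 19 water years 2001-2019, with an aridity gradient from a humid
    west to a hyper-arid east, snow at high elevations in the north, 2%
    composite-level noise, and 10% negative (cloud-like) outliers.
    """

    grid_size: int = 64
    n_years: int = 19
    first_year: int = 2001
    composites_per_year: int = COMPOSITES_PER_YEAR
    noise_sd: float = 0.02
    annual_noise_sd: float = 0.01
    outlier_rate: float = 0.10
    outlier_flagged_fraction: float = 0.9
    snow_ndvi: float = -0.05
    seed: Optional[int] = None

    # meteorology
    met_block: int = 8              # NDVI pixels per met cell, per side
    tp_west_mm: float = 600.0       # annual precipitation at the humid edge
    tp_east_mm: float = 50.0        # ... at the hyper-arid edge
    pev_west_mm: float = 900.0      # |potential evaporation| magnitudes
    pev_east_mm: float = 2500.0
    t2m_base_k: float = 288.0
    warming_trend: float = 0.045    # K per year
    tp_interannual_sd: float = 0.25  # relative sd of the shared wet/dry anomaly
    t2m_noise_sd: float = 0.3

    # snow (counted in 16-day composites, placed in winter)
    snow_max_composites: int = 6    # 0 disables snow entirely
    snow_elev_threshold_m: float = 1800.0

    # scripted bare -> cropland conversions (newly cultivated fields)
    conversion_fraction: float = 0.03   # fraction of bare pixels converted
    conversion_year_index: int = 4      # first water year of cultivation

    # irrigation: single-cycle crops below this long-term aridity are irrigated
    crop_irrigation_ai_threshold: float = 0.25

    # ancillary
    crop_fine_factor: int = 2       # fine cells per NDVI pixel, per side
    lc_flip_scale: float = 30.0     # scripted sparse<->bare flips per unit anomaly
    n_basins: int = 4
    twsa_trend_mm: float = -10.0    # mm equivalent water height per year
    twsa_seasonal_mm: float = 40.0
    twsa_noise_mm: float = 5.0
    twsa_gap_months: Optional[list[int]] = None  # indices into the monthly series
    dem_max_m: float = 3200.0

    class_params: Optional[dict[str, ClassParams]] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("GeneratorConfig requires an explicit seed "
                             "(reproducibility contract)")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3")
        if not (0.0 <= self.outlier_rate < 0.5):
            raise ValueError("outlier_rate must be in [0, 0.5)")
        if self.composites_per_year != COMPOSITES_PER_YEAR:
            raise ValueError("only 23 composites per water year are supported")
        if self.grid_size % self.met_block:
            # one met cell must cover a whole block of NDVI pixels
            self.met_block = max(
                b for b in range(1, self.met_block + 1)
                if self.grid_size % b == 0)
        if self.class_params is None:
            self.class_params = default_class_params(self.n_years)

    @property
    def years(self) -> np.ndarray:
        """Water-year labels of the simulated period."""
        return np.arange(self.first_year, self.first_year + self.n_years)

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["class_params"] = {
            k: asdict(v) for k, v in (self.class_params or {}).items()
        }
        return d
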