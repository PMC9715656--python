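"""Annual vegetation-growth aggregates per water year.

The central statistic is NDVI_MEAN*: the mean of the X highest NDVI
composites of a water year, where X is fixed per pixel (but constant over
years) from the maximum snow duration observed at that pixel.  Excluding
the snow period keeps interpolation artefacts from long snow cover out of
the annual mean while the inter-annual fixation of X keeps the statistic
comparable across years with different snow conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import COMPOSITES_PER_YEAR


@dataclass
class SnowStats:
    """Per-pixel maximum snow duration and the derived top-X count.

    ``max_snow_composites`` is the highest number of snow-flagged 16-day
    composites of any water year; X = max(23 - max_snow_composites - 1, 1),
    the extra -1 being a safety margin against partially snowy composites.
    """

    max_snow_composites: np.ndarray
    x: np.ndarray


def x_from_max_snow(max_snow: np.ndarray, calendar_days: bool = False
                    ) -> np.ndarray:
    """Number of top NDVI values entering the annual mean.

    With ``calendar_days=True`` the input is interpreted as calendar snow
    days and converted to composites by ceil(days / 16).
    """
    max_snow = np.asarray(max_snow)
    if calendar_days:
        max_snow = np.ceil(max_snow / 16.0).astype(int)
    return np.maximum(COMPOSITES_PER_YEAR - max_snow - 1, 1)


def max_snow_composites(snow_flags: np.ndarray, n_years: int | None = None,
                        calendar_days: bool = False) -> SnowStats:
    """Per-pixel snow statistics from per-composite snow flags.

    ``snow_flags`` has shape (..., n_years * 23); counts are taken per water
    year and the maximum over years defines the snow duration.
    """
    snow_flags = np.asarray(snow_flags, dtype=bool)
    T = snow_flags.shape[-1]
    if T % COMPOSITES_PER_YEAR != 0:
        raise ValueError("snow flag series must cover whole water years")
    ny = T // COMPOSITES_PER_YEAR
    if n_years is not None and ny != n_years:
        raise ValueError("missing years in snow flag series")
    counts = snow_flags.reshape(*snow_flags.shape[:-1], ny,
                                COMPOSITES_PER_YEAR).sum(axis=-1)
    max_snow = counts.max(axis=-1)
    return SnowStats(max_snow_composites=max_snow,
                     x=x_from_max_snow(max_snow, calendar_days=calendar_days))


def ndvi_mean_star(year_values: np.ndarray, x: int) -> float:
    """Mean of the X largest of the 23 composite values of one water year."""
    year_values = np.asarray(year_values, dtype=float)
    if year_values.shape[-1] != COMPOSITES_PER_YEAR:
        raise ValueError("a water year has exactly 23 composites")
    if not (1 <= int(x) <= COMPOSITES_PER_YEAR):
        raise ValueError("X out of range [1, 23]")
    top = np.sort(year_values, axis=-1)[..., COMPOSITES_PER_YEAR - int(x):]
    return top.mean(axis=-1)


@dataclass
class AnnualVegGrowth:
    """Per-pixel, per-water-year vegetation growth aggregates."""

    ndvi_mean_star: np.ndarray   # (ny, nx, n_years)
    ndvi_max: np.ndarray         # (ny, nx, n_years)
    long_term_mean: np.ndarray   # (ny, nx)
    years: np.ndarray
    x: np.ndarray                # (ny, nx) top-X count used


def annual_cube(smoothed: np.ndarray, snow: SnowStats,
                years: np.ndarray) -> AnnualVegGrowth:
    """Annual NDVI_MEAN* / NDVI_MAX cube from a smoothed composite cube.

    ``smoothed`` has shape (ny, nx, n_years * 23); only whole water years
    are accepted (trim partial years upstream).
    """
    smoothed = np.asarray(smoothed, dtype=float)
    ny, nx, T = smoothed.shape
    if T % COMPOSITES_PER_YEAR != 0:
        raise ValueError("cube must contain whole water years only")
    n_years = T // COMPOSITES_PER_YEAR
    if len(years) != n_years:
        raise ValueError("year labels do not match the cube length")
    yearly = smoothed.reshape(ny, nx, n_years, COMPOSITES_PER_YEAR)
    srt = np.sort(yearly, axis=-1)
    ndvi_max = srt[..., -1]
    # cumulative means of the k largest values, k = 1..23
    cum = np.cumsum(srt[..., ::-1], axis=-1)
    kmeans = cum / np.arange(1, COMPOSITES_PER_YEAR + 1)
    x = np.asarray(snow.x)
    if x.shape != (ny, nx):
        x = np.broadcast_to(x, (ny, nx))
    mean_star = np.take_along_axis(
        kmeans, (x[:, :, None, None] - 1).astype(int), axis=-1)[..., 0]
    return AnnualVegGrowth(
        ndvi_mean_star=mean_star,
        ndvi_max=ndvi_max,
        long_term_mean=mean_star.mean(axis=-1),
        years=np.asarray(years),
        x=np.broadcast_to(np.asarray(snow.x), (ny, nx)),
    )
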