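"""Monthly irrigation probability and annual irrigation intensity.

The monthly irrigation probability of a pixel is the product of three
factors: the probability that the pixel is vegetated (from the monthly
maximum NDVI), the probability that it is cropland (from the aggregated
cropland fraction), and the probability that crops growing that month
needed non-meteorological water (from the two-month aridity index).  High
values mean green cropland under conditions too dry to support that growth
from rainfall, i.e. irrigation.

Annual irrigation intensity (IrrIntAnn4Q) averages the upper quartile --
the three largest -- of the twelve monthly probabilities of a water year.
Reported intensities carry a scaling factor of 100.
"""

from __future__ import annotations

import numpy as np

from .config import MONTHS_PER_YEAR, composite_month_index


def veg_prob(ndvi: np.ndarray) -> np.ndarray:
    """Probability of being vegetated from the monthly maximum NDVI.

    Exponential CDF ramp above the 0.2 greenness threshold:
    1 - exp(-(NDVI - 0.2)/0.08), 0 below 0.2.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    with np.errstate(invalid="ignore"):
        p = 1.0 - np.exp(-(ndvi - 0.2) / 0.08)
    p = np.where(ndvi < 0.2, 0.0, p)
    return np.where(np.isnan(ndvi), np.nan, p)


def crop_prob(crop_frac: np.ndarray, as_printed: bool = False) -> np.ndarray:
    """Probability of being cropland from the cropland fraction (percent).

    Undefined (NaN) below 20%, 1 above 40%, linear 0 -> 1 ramp between.
    ``as_printed=True`` adds the literal published "+1" offset on the ramp
    (values then exceed 1; audit use only).
    """
    cf = np.asarray(crop_frac, dtype=float)
    ramp = (cf - 20.0) / (40.0 - 20.0)
    if as_printed:
        ramp = ramp + 1.0
    p = np.where(cf > 40.0, 1.0, ramp)
    p = np.where(cf < 20.0, np.nan, p)
    return np.where(np.isnan(cf), np.nan, p)


def water_prob(ai2: np.ndarray) -> np.ndarray:
    """Probability that growth required irrigation, from the two-month
    aridity index: 1 below ai2 = 0.2, 0.2 above 0.65, linear in between;
    the range is exactly [0.2, 1].  NaN ai2 (first series month) propagates.
    """
    a = np.asarray(ai2, dtype=float)
    p = 1.0 - (a - 0.2) / (0.65 - 0.2) * 0.8
    p = np.where(a < 0.2, 1.0, p)
    p = np.where(a > 0.65, 0.2, p)
    return np.where(np.isnan(a), np.nan, p)


def irr_prob(veg_p: np.ndarray, crop_p: np.ndarray, water_p: np.ndarray
             ) -> np.ndarray:
    """IrrProb = VegProb * CropProb * WaterProb (NaN where CropProb is NaN)."""
    return np.asarray(veg_p) * np.asarray(crop_p) * np.asarray(water_p)


def monthly_max_ndvi(smoothed: np.ndarray) -> np.ndarray:
    """Resample 16-day composites to monthly maxima.

    ``smoothed`` has shape (..., n_years*23); output (..., n_years*12).
    Composites are assigned to the calendar month containing their start
    date; every month receives at least one composite.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    T = smoothed.shape[-1]
    if T % 23 != 0:
        raise ValueError("series must cover whole water years")
    n_years = T // 23
    month_of = composite_month_index()
    out = np.full(smoothed.shape[:-1] + (n_years * MONTHS_PER_YEAR,), np.nan)
    yearly = smoothed.reshape(*smoothed.shape[:-1], n_years, 23)
    for m in range(MONTHS_PER_YEAR):
        sel = month_of == m
        out[..., m::MONTHS_PER_YEAR] = yearly[..., sel].max(axis=-1)
    return out


def irr_int_ann_4q(monthly_irr_prob: np.ndarray, min_defined: int = 3
                   ) -> np.ndarray:
    """Annual irrigation intensity: mean of the three largest defined
    monthly IrrProb values per water year (the upper quartile of 12).

    Undefined (NaN) when fewer than ``min_defined`` months are defined.
    Input shape (..., n_years*12) -> output (..., n_years), on the raw
    [0, 1] scale (apply the x100 reporting factor downstream).
    """
    p = np.asarray(monthly_irr_prob, dtype=float)
    T = p.shape[-1]
    if T % MONTHS_PER_YEAR != 0:
        raise ValueError("need 12 monthly values per water year")
    yearly = p.reshape(*p.shape[:-1], T // MONTHS_PER_YEAR, MONTHS_PER_YEAR)
    n_def = np.sum(~np.isnan(yearly), axis=-1)
    filled = np.where(np.isnan(yearly), -np.inf, yearly)
    top3 = np.sort(filled, axis=-1)[..., -3:]
    with np.errstate(invalid="ignore"):
        intensity = np.where(n_def >= min_defined, top3.mean(axis=-1), np.nan)
    return intensity


def initial_intensity(annual_intensity: np.ndarray, years: np.ndarray,
                      early_years: tuple = (2001, 2002, 2003),
                      scaled: bool = True) -> np.ndarray:
    """Mean annual intensity over the configured early period (default the
    three water years 2001-2003), scaled by 100 for reporting."""
    years = np.asarray(years)
    sel = np.isin(years, np.asarray(early_years))
    if not sel.any():
        raise ValueError("none of the early years are in the series")
    m = np.asarray(annual_intensity, dtype=float)[..., sel].mean(axis=-1)
    return 100.0 * m if scaled else m


def irrigation_fields(monthly_ndvi_max: np.ndarray, crop_frac: np.ndarray,
                      ai2_monthly: np.ndarray, as_printed: bool = False):
    """Monthly VegProb/CropProb/WaterProb/IrrProb and annual intensity.

    ``monthly_ndvi_max`` is (ny, nx, n_years*12); ``crop_frac`` (ny, nx);
    ``ai2_monthly`` already resampled to the pixel grid, same shape as the
    NDVI months.  Returns a dict of arrays.
    """
    vp = veg_prob(monthly_ndvi_max)
    cp = crop_prob(crop_frac, as_printed=as_printed)
    wp = water_prob(ai2_monthly)
    ip = irr_prob(vp, cp[..., None], wp)
    ann = irr_int_ann_4q(ip)
    return {"veg_prob": vp, "crop_prob": cp, "water_prob": wp,
            "irr_prob": ip, "irr_int_ann_4q": ann}
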