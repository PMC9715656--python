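"""Vegetation masks: vegetated / agricultural / natural / newly cultivated.

A pixel is *vegetated* if its annual NDVI maximum exceeds 0.25 in at least
two years.  Cropland is defined from the aggregated cropland fraction
(CropFrac, percent): *agricultural* above 20%, *natural* below 40% -- the
band (20, 40) deliberately belongs to both, absorbing mixed pixels and
fraction-product uncertainty.  Agricultural pixels that only became
cultivated after the period start are flagged so trend-vs-irrigation
analyses can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class VegClassMasks:
    vegetated: np.ndarray
    agricultural: np.ndarray
    natural: np.ndarray
    newly_cultivated: np.ndarray | None = None


def classify_vegetated(ndvi_max: np.ndarray, threshold: float = 0.25,
                       min_years: int = 2) -> np.ndarray:
    """True where the annual NDVI maximum exceeds ``threshold`` in at least
    ``min_years`` years.  ``ndvi_max`` has shape (..., n_years)."""
    ndvi_max = np.asarray(ndvi_max)
    if ndvi_max.shape[-1] < min_years:
        raise ValueError("need at least %d years" % min_years)
    return (ndvi_max > threshold).sum(axis=-1) >= min_years


def classify_agri_natural(crop_frac: np.ndarray, vegetated: np.ndarray,
                          agri_threshold: float = 20.0,
                          natural_threshold: float = 40.0) -> VegClassMasks:
    """Agricultural (CropFrac > 20) and natural (vegetated and CropFrac < 40)
    masks; comparisons are strict, so the thresholds themselves fall outside
    the respective class."""
    crop_frac = np.asarray(crop_frac, dtype=float)
    if np.any((crop_frac < 0) | (crop_frac > 100)):
        raise ValueError("crop fraction must be within [0, 100] percent")
    vegetated = np.asarray(vegetated, dtype=bool)
    agricultural = vegetated & (crop_frac > agri_threshold)
    natural = vegetated & (crop_frac < natural_threshold)
    return VegClassMasks(vegetated=vegetated, agricultural=agricultural,
                         natural=natural)


def flag_newly_cultivated(ndvi_max: np.ndarray, years: np.ndarray,
                          diff_threshold: float = 0.1,
                          initial_threshold: float = 0.3,
                          as_printed: bool = False) -> np.ndarray:
    """Flag pixels cultivated only after the period start.

    Compares the median annual NDVI maximum of the first three years
    (MedNDVI_MAXf3) against that of the late window 2009-2019
    (MedNDVI_MAXl10, the last eleven labels): a pixel is newly cultivated
    when the late median exceeds the early one by more than 0.1 while the
    early median stays below 0.3 (low initial greenness, i.e. not yet
    cultivated).  ``as_printed=True`` restores the literal published sign
    (f3 - l10 > 0.1) for audit.
    """
    ndvi_max = np.asarray(ndvi_max, dtype=float)
    years = np.asarray(years)
    n = ndvi_max.shape[-1]
    if n != len(years) or n < 14:
        raise ValueError("series must cover the first 3 and last 11 years")
    med_f3 = np.median(ndvi_max[..., :3], axis=-1)
    med_l10 = np.median(ndvi_max[..., -11:], axis=-1)
    diff = (med_f3 - med_l10) if as_printed else (med_l10 - med_f3)
    return (diff > diff_threshold) & (med_f3 < initial_threshold)


def area_summary(masks: VegClassMasks, pixel_area_km2: float = 0.0625):
    """Pixel counts and km2 per class, as plain records for a CSV table."""
    rows = []
    for name in ("vegetated", "agricultural", "natural"):
        m = getattr(masks, name)
        rows.append({"class": name, "pixel_count": int(m.sum()),
                     "area_km2": float(m.sum() * pixel_area_km2)})
    both = masks.agricultural & masks.natural
    rows.append({"class": "overlap(20-40)", "pixel_count": int(both.sum()),
                 "area_km2": float(both.sum() * pixel_area_km2)})
    return rows
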