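"""High-quality NDVI time-series reconstruction.

Three steps, applied to the continuous multi-year composite series of each
pixel: (I) mask composites whose quality code marks them degraded
(VIQuality > 2) or possibly snow/ice covered; (II) fill masked positions by
linear interpolation between the closest unmasked neighbours in time
(nearest-value extension at the series edges); (III) iterative
Savitzky-Golay smoothing toward the upper NDVI envelope, under the model
that residual noise (clouds, poor atmospheric conditions) only lowers NDVI.

The envelope iteration follows the local smoothing scheme of Chen et al.:
each pass replaces values lying below the current fit by the fitted value,
re-fits, and tracks a weighted fitting-effect index; the fit of the
best-index iteration is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

from .synthetic import NDVICube


@dataclass
class SmoothingConfig:
    window_length: int = 7
    poly_order: int = 2
    max_iterations: int = 10

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0 or self.window_length < 5:
            raise ValueError("window_length must be odd and >= 5")
        if self.poly_order >= self.window_length:
            raise ValueError("poly_order must be < window_length")


@dataclass
class CompositeSeries:
    """One pixel's composite series with aligned QA arrays."""

    values: np.ndarray
    qa_quality: np.ndarray
    qa_snow: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.values)
        if len(self.qa_quality) != n or len(self.qa_snow) != n:
            raise ValueError("QA arrays must align with values")


def mask_outliers(series: CompositeSeries) -> CompositeSeries:
    """Mask composites with VIQuality > 2 or the possible-snow/ice flag set."""
    mask = (np.asarray(series.qa_quality) > 2) | np.asarray(series.qa_snow,
                                                            dtype=bool)
    if mask.all():
        raise ValueError("all composites masked; nothing to interpolate from")
    return CompositeSeries(values=series.values.copy(),
                           qa_quality=series.qa_quality,
                           qa_snow=series.qa_snow,
                           mask=mask)


def interpolate_gaps(series: CompositeSeries) -> CompositeSeries:
    """Linearly fill masked positions from the closest unmasked composites.

    Leading/trailing gaps are filled with the nearest valid value.  The
    series is treated as continuous across water-year boundaries.
    """
    if series.mask is None:
        raise ValueError("run mask_outliers first")
    valid = ~series.mask
    if valid.sum() < 2:
        raise ValueError("need at least 2 unmasked composites")
    t = np.arange(len(series.values))
    filled = series.values.copy().astype(float)
    filled[series.mask] = np.interp(t[series.mask], t[valid],
                                    series.values[valid])
    return CompositeSeries(values=filled, qa_quality=series.qa_quality,
                           qa_snow=series.qa_snow, mask=series.mask)


def _envelope_iterate(orig: np.ndarray, cfg: SmoothingConfig
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised envelope iteration over the last axis.

    Returns (best fit, flag of rows that never improved past max_iterations).
    """
    orig = np.atleast_2d(orig)
    if cfg.window_length > orig.shape[-1]:
        raise ValueError("window longer than series")
    fit0 = savgol_filter(orig, cfg.window_length, cfg.poly_order, axis=-1)
    d = np.abs(orig - fit0)
    dmax = d.max(axis=-1, keepdims=True)
    dmax = np.where(dmax == 0, 1.0, dmax)
    # envelope points (on/above the first fit) get full weight
    w = np.where(orig >= fit0, 1.0, 1.0 - d / dmax)

    best_fit = fit0.copy()
    best_index = np.abs(fit0 - orig).__mul__(w).sum(axis=-1)
    prev_index = best_index.copy()
    work = np.where(orig >= fit0, orig, fit0)
    still_decreasing = np.ones(orig.shape[0], dtype=bool)
    non_converged = np.ones(orig.shape[0], dtype=bool)
    for _ in range(1, cfg.max_iterations):
        fit = savgol_filter(work, cfg.window_length, cfg.poly_order, axis=-1)
        index = (np.abs(fit - orig) * w).sum(axis=-1)
        improved = still_decreasing & (index < best_index)
        best_fit[improved] = fit[improved]
        best_index[improved] = index[improved]
        stopped = still_decreasing & (index >= prev_index)
        non_converged[stopped] = False
        still_decreasing &= ~stopped
        if not still_decreasing.any():
            break
        prev_index = index
        work = np.where(orig >= fit, orig, fit)
    return np.clip(best_fit, -1.0, 1.0), non_converged


def upper_envelope_smooth(series: CompositeSeries,
                          cfg: Optional[SmoothingConfig] = None
                          ) -> CompositeSeries:
    """Iterative Savitzky-Golay fit approaching the upper NDVI envelope."""
    cfg = cfg or SmoothingConfig()
    if series.mask is not None and bool(np.asarray(series.mask).any()):
        if np.isnan(series.values).any():
            raise ValueError("series must be gap-free (interpolate first)")
    fit, _ = _envelope_iterate(series.values[None, :], cfg)
    return CompositeSeries(values=fit[0], qa_quality=series.qa_quality,
                           qa_snow=series.qa_snow, mask=series.mask)


def reconstruct_series(values: np.ndarray, qa_quality: np.ndarray,
                       qa_snow: np.ndarray,
                       cfg: Optional[SmoothingConfig] = None) -> np.ndarray:
    """Full per-series reconstruction: mask -> interpolate -> envelope."""
    s = mask_outliers(CompositeSeries(np.asarray(values, dtype=float),
                                      np.asarray(qa_quality),
                                      np.asarray(qa_snow)))
    s = interpolate_gaps(s)
    return upper_envelope_smooth(s, cfg).values


@dataclass
class ReconstructionResult:
    smoothed: np.ndarray         # (ny, nx, T)
    filled: np.ndarray           # after masking + interpolation
    mask: np.ndarray             # (ny, nx, T) bool, True = was masked
    skipped: np.ndarray          # (ny, nx) bool, pixels with < 2 valid composites
    mask_fraction: float = field(default=0.0)


def reconstruct_cube(cube: NDVICube,
                     cfg: Optional[SmoothingConfig] = None
                     ) -> ReconstructionResult:
    """Reconstruct every pixel series of an NDVI cube.

    Pixels with fewer than two unmasked composites are left unreconstructed
    and flagged in ``skipped``.
    """
    cfg = cfg or SmoothingConfig()
    ny, nx, T = cube.ndvi.shape
    mask = (cube.qa_quality > 2) | cube.qa_snow
    values = cube.ndvi.reshape(-1, T)
    mflat = mask.reshape(-1, T)
    filled = values.astype(float).copy()
    skipped = np.zeros(ny * nx, dtype=bool)
    t = np.arange(T)
    for i in range(ny * nx):
        m = mflat[i]
        if not m.any():
            continue
        valid = ~m
        if valid.sum() < 2:
            skipped[i] = True
            continue
        filled[i, m] = np.interp(t[m], t[valid], values[i, valid])
    ok = ~skipped
    smoothed = filled.copy()
    if ok.any():
        smoothed[ok], _ = _envelope_iterate(filled[ok], cfg)
    return ReconstructionResult(
        smoothed=smoothed.reshape(ny, nx, T),
        filled=filled.reshape(ny, nx, T),
        mask=mask,
        skipped=skipped.reshape(ny, nx),
        mask_fraction=float(mask.mean()),
    )
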