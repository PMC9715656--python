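"""Grid resampling between the pixel grid, the coarse met grid and the fine
crop-fraction grid.

All grids in the pipeline are axis-aligned with integer block ratios and
pixel-centre registration, so resampling reduces to exact block operations:
nearest neighbour = block replication of the containing coarse cell,
average = block mean of the contributing fine cells, bilinear = standard
4-neighbour weighting on pixel centres.
"""

from __future__ import annotations

import numpy as np


def nearest_upsample(coarse: np.ndarray, factor: int) -> np.ndarray:
    """Replicate each coarse cell over a factor x factor block of pixels.

    Works on (ny, nx) or (ny, nx, t) arrays; the trailing axes are kept.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    out = np.repeat(np.asarray(coarse), factor, axis=0)
    return np.repeat(out, factor, axis=1)


def block_average(fine: np.ndarray, factor: int) -> np.ndarray:
    """Block mean of factor x factor fine cells per output cell."""
    fine = np.asarray(fine, dtype=float)
    ny, nx = fine.shape[:2]
    if ny % factor or nx % factor:
        raise ValueError("grid not divisible by factor (non-overlapping extents)")
    shaped = fine.reshape(ny // factor, factor, nx // factor, factor,
                          *fine.shape[2:])
    return shaped.mean(axis=(1, 3))


def bilinear_upsample(coarse: np.ndarray, factor: int) -> np.ndarray:
    """Bilinear interpolation of coarse cell centres onto the fine grid.

    Fine pixel centres outside the hull of coarse centres are clamped to
    the edge value (constant extrapolation).
    """
    coarse = np.asarray(coarse, dtype=float)
    ny, nx = coarse.shape
    fy = (np.arange(ny * factor) + 0.5) / factor - 0.5
    fx = (np.arange(nx * factor) + 0.5) / factor - 0.5
    fy = np.clip(fy, 0, ny - 1)
    fx = np.clip(fx, 0, nx - 1)
    y0 = np.floor(fy).astype(int)
    x0 = np.floor(fx).astype(int)
    y1 = np.minimum(y0 + 1, ny - 1)
    x1 = np.minimum(x0 + 1, nx - 1)
    wy = (fy - y0)[:, None]
    wx = (fx - x0)[None, :]
    return ((1 - wy) * (1 - wx) * coarse[np.ix_(y0, x0)]
            + (1 - wy) * wx * coarse[np.ix_(y0, x1)]
            + wy * (1 - wx) * coarse[np.ix_(y1, x0)]
            + wy * wx * coarse[np.ix_(y1, x1)])


def resample(raster: np.ndarray, target_shape: tuple, method: str
             ) -> np.ndarray:
    """Resample ``raster`` to ``target_shape`` (2D) by the named method."""
    src = np.asarray(raster)
    sy, sx = src.shape[:2]
    ty, tx = target_shape
    if ty >= sy:  # upsampling
        if ty % sy or tx % sx:
            raise ValueError("non-integer grid ratio")
        f = ty // sy
        if method == "nearest":
            return nearest_upsample(src, f)
        if method == "bilinear":
            return bilinear_upsample(src, f)
        if method == "average":
            return nearest_upsample(src, f)  # average of one cell = itself
    else:  # downsampling
        if sy % ty or sx % tx:
            raise ValueError("non-integer grid ratio")
        f = sy // ty
        if method == "average":
            return block_average(src, f)
        if method == "nearest":
            # centre-of-block nearest: pick the cell containing the centre
            return src[f // 2::f, f // 2::f]
    raise ValueError("unknown method %r" % method)
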