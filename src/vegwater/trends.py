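"""Monotonic trend detection on annual series.

Magnitude: Theil-Sen slope (median of all pairwise slopes).  Significance:
Mann-Kendall test with the Hamed-Rao variance correction, which inflates
the variance of the S statistic by the significant rank autocorrelations of
the series so that serially dependent annual series (e.g. drought
carry-over effects) do not produce spurious significance.

All statistics are computed with exact integer pair enumeration (n is
small: one value per water year), vectorised over pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TrendResult:
    slope: float
    intercept: float
    s_statistic: int
    variance: float
    z: float
    p_value: float
    n: int
    significant: bool


def theil_sen(series: np.ndarray, t: np.ndarray | None = None
              ) -> tuple[float, float]:
    """Theil-Sen slope and intercept of a single series.

    slope = median over all pairwise slopes (x_j - x_i)/(t_j - t_i), j > i;
    intercept = median(x - slope * t).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 points")
    t = np.arange(n, dtype=float) if t is None else np.asarray(t, dtype=float)
    if np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct time points")
    i, j = np.triu_indices(n, k=1)
    keep = t[j] != t[i]
    slopes = (x[j][keep] - x[i][keep]) / (t[j][keep] - t[i][keep])
    slope = float(np.median(slopes))
    return slope, float(np.median(x - slope * t))


def _s_statistic(x: np.ndarray) -> np.ndarray:
    """Mann-Kendall S per row; x has shape (N, n)."""
    diff = np.sign(x[:, None, :] - x[:, :, None])   # (N, i, j) = sign(x_j - x_i)
    iu = np.triu_indices(x.shape[1], k=1)
    return diff[:, iu[0], iu[1]].sum(axis=1)


def _tie_term(x: np.ndarray) -> np.ndarray:
    """Per-row tie correction sum: sum over tie groups of t(t-1)(2t+5)."""
    N, n = x.shape
    out = np.zeros(N)
    for r in range(N):
        _, counts = np.unique(x[r], return_counts=True)
        ties = counts[counts > 1]
        if ties.size:
            out[r] = np.sum(ties * (ties - 1) * (2 * ties + 5))
    return out


def _rank_autocorr(ranks: np.ndarray, lag: int) -> np.ndarray:
    """Lag-``lag`` sample autocorrelation of the ranks, per row."""
    c = ranks - ranks.mean(axis=1, keepdims=True)
    denom = (c ** 2).sum(axis=1)
    num = (c[:, lag:] * c[:, :-lag]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, num / denom, 0.0)


def _mk_arrays(x: np.ndarray, alpha: float = 0.05,
               variance_floor_ratio: float = 1e-2):
    """Vectorised Mann-Kendall with Hamed-Rao correction; x is (N, n)."""
    x = np.asarray(x, dtype=float)
    N, n = x.shape
    if n < 4:
        raise ValueError("need at least 4 observations")
    S = _s_statistic(x)
    var0 = (n * (n - 1) * (2 * n + 5) - _tie_term(x)) / 18.0

    ranks = stats.rankdata(x, axis=1)
    ratio = np.ones(N)
    crit = stats.norm.ppf(0.975) / np.sqrt(n)
    for lag in range(1, n - 2):          # lags 1 .. n-3
        rho = _rank_autocorr(ranks, lag)
        w = (n - lag) * (n - lag - 1) * (n - lag - 2)
        ratio += np.where(np.abs(rho) > crit,
                          2.0 / (n * (n - 1) * (n - 2)) * w * rho, 0.0)
    ratio = np.maximum(ratio, variance_floor_ratio)
    var = np.maximum(var0 * ratio, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(S > 0, (S - 1) / np.sqrt(var),
                     np.where(S < 0, (S + 1) / np.sqrt(var), 0.0))
    z = np.where(var == 0, 0.0, z)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(var == 0, 1.0, p)
    return S.astype(int), var0, var, z, p


def mann_kendall_hamed_rao(series: np.ndarray, alpha: float = 0.05
                           ) -> TrendResult:
    """Mann-Kendall trend test with autocorrelation-corrected variance."""
    x = np.asarray(series, dtype=float)
    S, var0, var, z, p = _mk_arrays(x[None, :], alpha=alpha)
    slope, intercept = theil_sen(x)
    return TrendResult(slope=slope, intercept=intercept,
                       s_statistic=int(S[0]), variance=float(var[0]),
                       z=float(z[0]), p_value=float(p[0]), n=x.size,
                       significant=bool(p[0] < alpha))


@dataclass
class TrendMaps:
    slope: np.ndarray
    p_value: np.ndarray
    z: np.ndarray
    s_statistic: np.ndarray
    significant: np.ndarray
    skipped: np.ndarray
    alpha: float


def trend_map(annual_values: np.ndarray, alpha: float = 0.05,
              year_subset: np.ndarray | None = None) -> TrendMaps:
    """Per-pixel Theil-Sen slope and corrected Mann-Kendall significance.

    ``annual_values`` has shape (ny, nx, n_years); ``year_subset`` (boolean
    or index along the year axis) reproduces sensitivity runs that drop
    e.g. the dry start years and a wet final year.  Pixels containing NaN
    years are skipped and flagged.
    """
    vals = np.asarray(annual_values, dtype=float)
    if year_subset is not None:
        vals = vals[..., year_subset]
    ny, nx, n = vals.shape
    flat = vals.reshape(-1, n)
    skipped = np.isnan(flat).any(axis=1)
    ok = ~skipped
    slope = np.full(ny * nx, np.nan)
    p = np.full(ny * nx, np.nan)
    z = np.full(ny * nx, np.nan)
    S = np.zeros(ny * nx, dtype=int)
    if ok.any():
        x = flat[ok]
        S_ok, _, _, z_ok, p_ok = _mk_arrays(x, alpha=alpha)
        i, j = np.triu_indices(n, k=1)
        pair_slopes = (x[:, j] - x[:, i]) / (j - i)
        slope[ok] = np.median(pair_slopes, axis=1)
        p[ok], z[ok], S[ok] = p_ok, z_ok, S_ok
    sig = (p < alpha) & ~np.isnan(p)
    shape = (ny, nx)
    return TrendMaps(slope=slope.reshape(shape), p_value=p.reshape(shape),
                     z=z.reshape(shape), s_statistic=S.reshape(shape),
                     significant=sig.reshape(shape),
                     skipped=skipped.reshape(shape), alpha=alpha)


def basin_trend_shares(trend: TrendMaps, basin_id: np.ndarray,
                       mask: np.ndarray) -> pd.DataFrame:
    """Per-basin counts and shares of significant positive/negative trends
    within ``mask`` (typically the agricultural mask)."""
    basin_id = np.asarray(basin_id)
    mask = np.asarray(mask, dtype=bool)
    rows = []
    for bid in np.unique(basin_id):
        sel = (basin_id == bid) & mask
        sig = sel & trend.significant
        pos = int((sig & (trend.slope > 0)).sum())
        neg = int((sig & (trend.slope < 0)).sum())
        total_sig = pos + neg
        rows.append({
            "basin_id": int(bid),
            "n_pixels": int(sel.sum()),
            "n_significant": total_sig,
            "n_positive": pos,
            "n_negative": neg,
            "share_positive_pct": 100.0 * pos / total_sig if total_sig else 0.0,
            "share_negative_pct": 100.0 * neg / total_sig if total_sig else 0.0,
        })
    return pd.DataFrame(rows)
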