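"""Pearson correlation analyses linking vegetation growth to meteorology
and total water storage, plus binned (elevation / R^2 / intensity)
summaries.

Correlations are computed per pixel over the common water years; p-values
use the t-distribution with n-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hydromet import AnnualTwsa, zscores
from .resample import nearest_upsample

MET_PRIORITY = ("ai", "tp", "t2m")   # tie-break order for the argmax map

ARIDITY_BREAKS = (
    ("hyper-arid", 0.0, 0.05),
    ("arid", 0.05, 0.2),
    ("semi-arid", 0.2, 0.5),
    ("dry sub-humid", 0.5, 0.65),
    ("humid", 0.65, np.inf),
)


def pearson_r_p(x: np.ndarray, y: np.ndarray):
    """Row-wise Pearson R and two-sided p over the last axis, NaN-safe only
    in the sense that rows containing NaN return NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[-1]
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum(axis=-1) * (yc ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc * yc).sum(axis=-1) / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-15))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return r, p


@dataclass
class CorrelationMaps:
    r: dict            # parameter -> (ny, nx) Pearson R
    p: dict            # parameter -> (ny, nx) p-value
    r2_max: np.ndarray
    argmax_param: np.ndarray   # (ny, nx) of parameter names ('' outside mask)


def pixelwise_met_correlation(veg_annual: np.ndarray,
                              met_annual: dict[str, np.ndarray],
                              met_block: int,
                              mask: np.ndarray | None = None
                              ) -> CorrelationMaps:
    """Per-pixel Pearson correlation of NDVI_MEAN* with annual met parameters.

    ``met_annual`` maps parameter name -> (ncy, ncx, n_years) coarse-grid
    annual series, resampled to the pixel grid by nearest neighbour.  The
    highest-R^2 parameter per pixel is reported with deterministic
    tie-break priority ai > tp > t2m.
    """
    veg = np.asarray(veg_annual, dtype=float)
    ny, nx, n = veg.shape
    if n < 4:
        raise ValueError("need at least 4 common years")
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    r_maps, p_maps = {}, {}
    for name, cell in met_annual.items():
        pix = nearest_upsample(cell, met_block)[:ny, :nx]
        r, p = pearson_r_p(veg.reshape(-1, n), pix.reshape(-1, n))
        r_maps[name] = np.where(mask, r.reshape(ny, nx), np.nan)
        p_maps[name] = np.where(mask, p.reshape(ny, nx), np.nan)
    r2_max = np.full((ny, nx), np.nan)
    argmax = np.full((ny, nx), "", dtype=object)
    for name in MET_PRIORITY:
        if name not in r_maps:
            continue
        r2 = r_maps[name] ** 2
        better = np.where(np.isnan(r2_max), ~np.isnan(r2),
                          r2 > r2_max)  # strict > keeps priority on ties
        r2_max = np.where(better, r2, r2_max)
        argmax = np.where(better, name, argmax)
    return CorrelationMaps(r=r_maps, p=p_maps, r2_max=r2_max,
                           argmax_param=argmax)


def bin_by(values: np.ndarray, key: np.ndarray, binwidth: float,
           origin: float = 0.0) -> pd.DataFrame:
    """Binned summary (median, quartiles, count) of ``values`` by ``key``.

    Bins are [origin + k*w, origin + (k+1)*w); empty bins between occupied
    ones are recorded with count 0 and no median.
    """
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    v = np.asarray(values, dtype=float).ravel()
    k = np.asarray(key, dtype=float).ravel()
    ok = ~(np.isnan(v) | np.isnan(k))
    v, k = v[ok], k[ok]
    if v.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count",
                                     "median", "q1", "q3"])
    idx = np.floor((k - origin) / binwidth).astype(int)
    rows = []
    for b in range(idx.min(), idx.max() + 1):
        sel = idx == b
        left = origin + b * binwidth
        row = {"bin_left": left, "bin_right": left + binwidth,
               "count": int(sel.sum())}
        if sel.any():
            row["median"] = float(np.median(v[sel]))
            row["q1"] = float(np.percentile(v[sel], 25))
            row["q3"] = float(np.percentile(v[sel], 75))
        else:
            row["median"] = np.nan
            row["q1"] = np.nan
            row["q3"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def iranwide_annual_correlation(veg_series: dict[str, np.ndarray],
                                met_series: dict[str, np.ndarray],
                                twsa_annual: np.ndarray | None = None,
                                reference: np.ndarray | None = None):
    """Country-averaged annual correlations of vegetation classes with
    hydrometeorology.

    ``veg_series``: class name (veg / vegAgr / vegNat) -> (n_years,) domain
    averages; ``met_series``: parameter -> (n_years,); ``twsa_annual`` may
    contain NaN at excluded years (dropped pairwise).  Returns (table,
    z-score dict over the reference period).
    """
    params = dict(met_series)
    if twsa_annual is not None:
        params["twsa"] = np.asarray(twsa_annual, dtype=float)
    rows = []
    for vname, v in veg_series.items():
        v = np.asarray(v, dtype=float)
        for pname, series in params.items():
            s = np.asarray(series, dtype=float)
            ok = ~(np.isnan(v) | np.isnan(s))
            if ok.sum() < 4:
                raise ValueError("fewer than 4 common years for %s/%s"
                                 % (vname, pname))
            r, p = pearson_r_p(v[ok], s[ok])
            rows.append({"veg_class": vname, "parameter": pname,
                         "r": float(r), "p": float(p), "n": int(ok.sum())})
    table = pd.DataFrame(rows)
    zs = {}
    for name, series in {**veg_series, **params}.items():
        s = np.asarray(series, dtype=float)
        ref = reference if reference is not None else ~np.isnan(s)
        zs[name] = zscores(np.where(np.isnan(s), np.nan, s), ref)
    return table, zs


def aridity_class(ai: np.ndarray) -> np.ndarray:
    """Standard aridity-index class labels (hyper-arid .. humid)."""
    ai = np.asarray(ai, dtype=float)
    out = np.full(ai.shape, "", dtype=object)
    for name, lo, hi in ARIDITY_BREAKS:
        out[(ai >= lo) & (ai < hi)] = name
    return out


def twsa_vegetation_correlation(veg_annual: np.ndarray,
                                twsa: AnnualTwsa,
                                basin_id: np.ndarray,
                                mask: np.ndarray,
                                intensity: np.ndarray | None = None,
                                aridity: np.ndarray | None = None,
                                r_threshold: float = 0.6,
                                intensity_threshold: float = 50.0):
    """Correlate each masked pixel's NDVI_MEAN* with its basin's annual TWSA.

    Excluded TWSA years are dropped pairwise.  Returns a dict with the R
    map, the per-basin share of highly positive (R > threshold) pixels, an
    R distribution binned by initial irrigation intensity, and -- for
    intensely irrigated pixels -- by aridity class.
    """
    veg = np.asarray(veg_annual, dtype=float)
    ny, nx, n = veg.shape
    mask = np.asarray(mask, dtype=bool)
    r_map = np.full((ny, nx), np.nan)
    shares = []
    for b, bid in enumerate(twsa.basin_ids):
        t_series = twsa.annual[b]
        ok_years = ~np.isnan(t_series)
        if ok_years.sum() < 4:
            raise ValueError("basin %s has fewer than 4 usable years" % bid)
        sel = (basin_id == bid) & mask
        if sel.any():
            r, _ = pearson_r_p(veg[sel][:, ok_years],
                               np.broadcast_to(t_series[ok_years],
                                               (int(sel.sum()),
                                                int(ok_years.sum()))))
            r_map[sel] = r
        n_pix = int(sel.sum())
        n_high = int((r_map[sel] > r_threshold).sum()) if n_pix else 0
        shares.append({"basin_id": int(bid), "n_pixels": n_pix,
                       "n_high_positive": n_high,
                       "share_high_positive_pct":
                           100.0 * n_high / n_pix if n_pix else 0.0})
    out = {"r_map": r_map, "basin_shares": pd.DataFrame(shares)}
    if intensity is not None:
        out["r_by_intensity"] = bin_by(r_map[mask], intensity[mask],
                                       binwidth=10.0)
        if aridity is not None:
            high = mask & (intensity > intensity_threshold)
            rows = []
            labels = aridity_class(aridity)
            for name, _, _ in ARIDITY_BREAKS:
                sel = high & (labels == name)
                vals = r_map[sel]
                vals = vals[~np.isnan(vals)]
                rows.append({"aridity_class": name, "count": int(vals.size),
                             "median_r": float(np.median(vals))
                             if vals.size else np.nan})
            out["r_by_aridity"] = pd.DataFrame(rows)
    return out
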