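"""Land-cover reclassification and change accounting.

Annual categorical maps in 22 raw classes (ESA-CCI-style codes) are merged
into 7 compound classes -- crops, trees, shrubs/sparse vegetation/
grassland, inundated, urban, bare, water -- to eliminate frequent
misclassifications among closely related raw classes (e.g. irrigated vs
rainfed cropland).  Change statistics cover per-class annual net rates
(gain - loss), cumulative change relative to the first year, first-to-last
transition matrices, and correlation of net rates with water-year
aggregated meteorology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MONTHS_PER_YEAR
from .correlations import pearson_r_p
from .synthetic import LC_CLASSES, LandCoverSeries

# Reconstructed default merge of the 22 ESA-CCI-style raw codes into the 7
# compound classes.  The authoritative per-project table is supplementary
# material of the source product; treat this mapping as editable
# configuration, not ground truth.
DEFAULT_RECLASS_MAP = {
    10: "crops",            # rainfed cropland
    20: "crops",            # irrigated cropland
    30: "crops",            # mosaic cropland / natural
    40: "shrubs/sparse vegetation/grassland",  # mosaic natural / cropland
    50: "trees",            # broadleaved evergreen
    60: "trees",            # broadleaved deciduous
    70: "trees",            # needleleaved evergreen
    80: "trees",            # needleleaved deciduous
    90: "trees",            # mixed leaf
    100: "shrubs/sparse vegetation/grassland",  # mosaic tree & shrub
    110: "shrubs/sparse vegetation/grassland",  # mosaic herbaceous
    120: "shrubs/sparse vegetation/grassland",  # shrubland
    130: "shrubs/sparse vegetation/grassland",  # grassland
    140: "shrubs/sparse vegetation/grassland",  # lichens and mosses
    150: "shrubs/sparse vegetation/grassland",  # sparse vegetation
    160: "inundated",       # flooded tree cover, fresh
    170: "inundated",       # flooded tree cover, saline
    180: "inundated",       # flooded shrub/herbaceous
    190: "urban",
    200: "bare",
    210: "water",
    220: "bare",            # permanent snow and ice
}


def reclassify(raw_map: np.ndarray,
               mapping: dict[int, str] | None = None) -> np.ndarray:
    """Merge raw class codes into the 7 compound classes (integer codes
    indexing ``LC_CLASSES``).  Raises on codes absent from the mapping."""
    mapping = DEFAULT_RECLASS_MAP if mapping is None else mapping
    raw_map = np.asarray(raw_map)
    code = {name: i for i, name in enumerate(LC_CLASSES)}
    lut = {}
    for raw, name in mapping.items():
        if name not in code:
            raise ValueError("unknown compound class %r" % name)
        lut[raw] = code[name]
    present = np.unique(raw_map)
    missing = [int(c) for c in present if int(c) not in lut]
    if missing:
        raise ValueError("unmapped raw class codes: %s" % missing)
    out = np.zeros(raw_map.shape, dtype=int)
    for raw, compound in lut.items():
        out[raw_map == raw] = compound
    return out


@dataclass
class ChangeStatistics:
    net_rate_km2: pd.DataFrame        # year x class, gain - loss
    gains_km2: pd.DataFrame
    losses_km2: pd.DataFrame
    cumulative_pct: pd.DataFrame      # % change of class area vs first year
    normalized_cumulative: pd.DataFrame   # min-max normalised area curves
    overall: pd.DataFrame             # first-vs-last gains and losses


def _areas(maps: np.ndarray, n_classes: int, pixel_area: float) -> np.ndarray:
    counts = np.stack([(maps == c).sum(axis=(1, 2))
                       for c in range(n_classes)], axis=1)
    return counts * pixel_area


def change_statistics(series: LandCoverSeries) -> ChangeStatistics:
    """Per-class annual gains/losses/net rates and cumulative change."""
    maps = np.asarray(series.maps)
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 annual maps")
    names = list(series.class_names)
    nc = len(names)
    a = series.pixel_area_km2
    years = np.asarray(series.years)

    gains = np.zeros((maps.shape[0], nc))
    losses = np.zeros((maps.shape[0], nc))
    for iy in range(1, maps.shape[0]):
        prev, cur = maps[iy - 1], maps[iy]
        changed = prev != cur
        for c in range(nc):
            gains[iy, c] = ((cur == c) & changed).sum() * a
            losses[iy, c] = ((prev == c) & changed).sum() * a
    net = gains - losses

    areas = _areas(maps, nc, a)
    first = areas[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        cum_pct = np.where(first > 0, 100.0 * (areas - first) / first, np.nan)
    span = areas.max(axis=0) - areas.min(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(span > 0, (areas - areas.min(axis=0)) / span, np.nan)

    overall_rows = []
    for c in range(nc):
        changed_in = ((maps[-1] == c) & (maps[0] != c)).sum() * a
        changed_out = ((maps[0] == c) & (maps[-1] != c)).sum() * a
        overall_rows.append({"class": names[c], "gain_km2": changed_in,
                             "loss_km2": changed_out,
                             "net_km2": changed_in - changed_out})

    def frame(arr):
        return pd.DataFrame(arr, index=years, columns=names)

    return ChangeStatistics(net_rate_km2=frame(net), gains_km2=frame(gains),
                            losses_km2=frame(losses),
                            cumulative_pct=frame(cum_pct),
                            normalized_cumulative=frame(norm),
                            overall=pd.DataFrame(overall_rows))


def transition_matrix(first_map: np.ndarray, last_map: np.ndarray,
                      class_names: tuple = LC_CLASSES,
                      pixel_area_km2: float = 0.0625) -> pd.DataFrame:
    """Area cross-tabulation from -> to between two maps (km^2)."""
    first_map = np.asarray(first_map)
    last_map = np.asarray(last_map)
    if first_map.shape != last_map.shape:
        raise ValueError("grid mismatch")
    nc = len(class_names)
    mat = np.zeros((nc, nc))
    flat = first_map.ravel() * nc + last_map.ravel()
    counts = np.bincount(flat, minlength=nc * nc).reshape(nc, nc)
    mat = counts * pixel_area_km2
    return pd.DataFrame(mat, index=list(class_names),
                        columns=list(class_names))


def top_transitions(matrix: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """The k largest off-diagonal transitions, ranked by area."""
    rows = []
    for i, frm in enumerate(matrix.index):
        for j, to in enumerate(matrix.columns):
            if i != j and matrix.iloc[i, j] > 0:
                rows.append({"from_class": frm, "to_class": to,
                             "area_km2": float(matrix.iloc[i, j])})
    out = pd.DataFrame(rows).sort_values("area_km2", ascending=False)
    out = out.head(k).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def windowed_met_aggregate(monthly: np.ndarray, window: int = 12
                           ) -> np.ndarray:
    """Water-year aggregates over ``window`` months ending each September.

    window=12 is the plain water year; window=15 prepends the previous
    three months (a prolonged window including the prior year's late
    conditions).  Years whose window would start before the series are NaN.
    """
    monthly = np.asarray(monthly, dtype=float)
    T = monthly.shape[-1]
    n_years = T // MONTHS_PER_YEAR
    out = np.full(monthly.shape[:-1] + (n_years,), np.nan)
    for iy in range(n_years):
        end = (iy + 1) * MONTHS_PER_YEAR
        start = end - window
        if start < 0:
            continue
        out[..., iy] = monthly[..., start:end].mean(axis=-1)
    return out


def netrate_met_correlation(net_rate: pd.DataFrame,
                            met_monthly: dict[str, np.ndarray],
                            windows: tuple = (12, 15)) -> pd.DataFrame:
    """Pearson correlation of class net rates with windowed met aggregates.

    ``met_monthly``: parameter -> country-mean monthly series aligned to
    the land-cover water years.  Net rates of the first year are undefined
    (no previous map) and dropped pairwise.
    """
    rows = []
    for cls in net_rate.columns:
        nr = net_rate[cls].to_numpy(dtype=float)
        nr[0] = np.nan          # no change rate for the first mapped year
        for pname, series in met_monthly.items():
            for w in windows:
                agg = windowed_met_aggregate(series, window=w)
                ok = ~(np.isnan(nr) | np.isnan(agg))
                if ok.sum() < 4:
                    raise ValueError("fewer than 4 overlapping years")
                r, p = pearson_r_p(nr[ok], agg[ok])
                rows.append({"class": cls, "parameter": "%s_%d" % (pname, w),
                             "r": float(r), "p": float(p),
                             "n": int(ok.sum())})
    return pd.DataFrame(rows)
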