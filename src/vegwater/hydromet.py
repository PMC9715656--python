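"""Water-year aggregation of meteorology, aridity indices, Z-scores, and
annualisation of basin total-water-storage-anomaly series.

All annual statistics run over the water year October-September.  Potential
evaporation follows the reanalysis sign convention (negative); aridity
indices are formed against its absolute value so that ai = tp/|pev| is a
positive dryness ratio (lower = drier).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .config import MONTHS_PER_YEAR
from .synthetic import TwsaSeries


def aggregate_water_year(monthly: np.ndarray, statistic: str = "mean"
                         ) -> np.ndarray:
    """Aggregate a monthly series (..., n_years*12) to water-year values.

    ``statistic``: "mean" (default, following annual averaging of the
    hydrometeorological parameters) or "sum".  Months must cover whole
    water years, October first.
    """
    monthly = np.asarray(monthly, dtype=float)
    T = monthly.shape[-1]
    if T % MONTHS_PER_YEAR != 0:
        raise ValueError("monthly series must cover whole water years")
    yearly = monthly.reshape(*monthly.shape[:-1], T // MONTHS_PER_YEAR,
                             MONTHS_PER_YEAR)
    if statistic == "mean":
        return yearly.mean(axis=-1)
    if statistic == "sum":
        return yearly.sum(axis=-1)
    raise ValueError("statistic must be 'mean' or 'sum'")


def aridity_index(tp_annual: np.ndarray, pev_annual: np.ndarray) -> np.ndarray:
    """Annual aridity index ai = tp / |pev| on water-year aggregates."""
    pev = np.abs(np.asarray(pev_annual, dtype=float))
    tp = np.asarray(tp_annual, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(pev > 0, tp / pev, np.nan)
    return ai


def two_month_ai(tp_monthly: np.ndarray, pev_monthly: np.ndarray) -> np.ndarray:
    """Two-month aridity index over the current and previous month.

    ai2(m) = (tp(m) + tp(m-1)) / |pev(m) + pev(m-1)|; the first month of
    the series has no previous month and is returned as NaN.
    """
    tp = np.asarray(tp_monthly, dtype=float)
    pev = np.asarray(pev_monthly, dtype=float)
    tp2 = tp[..., 1:] + tp[..., :-1]
    pev2 = np.abs(pev[..., 1:] + pev[..., :-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        ai2 = np.where(pev2 > 0, tp2 / pev2, np.nan)
    out = np.full(tp.shape, np.nan)
    out[..., 1:] = ai2
    return out


def zscores(annual: np.ndarray, reference: np.ndarray | slice | None = None
            ) -> np.ndarray:
    """Standardise an annual series against a reference period.

    ``reference`` selects the reference years along the last axis (boolean
    mask, index array or slice); by default the whole series is the
    reference.  The sample standard deviation (ddof=1) is used.
    """
    annual = np.asarray(annual, dtype=float)
    if reference is None:
        ref = annual
    else:
        ref = annual[..., reference]
    if ref.shape[-1] < 3:
        raise ValueError("reference period must span at least 3 years")
    mu = np.nanmean(ref, axis=-1, keepdims=True)
    sd = np.nanstd(ref, axis=-1, keepdims=True, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero variance in the reference period")
    return (annual - mu) / sd


@dataclass
class AnnualTwsa:
    basin_ids: np.ndarray
    annual: np.ndarray        # (n_basins, n_years), NaN at excluded years
    years: np.ndarray
    excluded_years: np.ndarray


def annualize_twsa(twsa: TwsaSeries, max_fill_gap: int = 1) -> AnnualTwsa:
    """Water-year averages of basin TWSA series.

    Isolated outage months (runs of length <= ``max_fill_gap``) are filled
    by cubic-spline interpolation over the month index; longer blocks --
    such as the 11-month inter-mission gap -- are left unfilled, and every
    water year overlapping an unfilled month is excluded from the annual
    series.
    """
    monthly = twsa.monthly.astype(float).copy()
    n_basins, T = monthly.shape
    n_years = T // MONTHS_PER_YEAR
    excluded = np.zeros(n_years, dtype=bool)
    for b in range(n_basins):
        s = monthly[b]
        isnan = np.isnan(s)
        if isnan.all():
            raise ValueError("basin %s has no data" % twsa.basin_ids[b])
        if not isnan.any():
            continue
        # identify runs of missing months
        idx = np.flatnonzero(isnan)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        valid = np.flatnonzero(~isnan)
        spline = CubicSpline(valid, s[valid])
        for run in runs:
            if len(run) <= max_fill_gap:
                s[run] = spline(run)
            else:
                excluded |= np.isin(np.arange(n_years),
                                    np.unique(run // MONTHS_PER_YEAR))
        monthly[b] = s
    yearly = monthly.reshape(n_basins, n_years, MONTHS_PER_YEAR)
    with np.errstate(invalid="ignore"):
        annual = np.nanmean(yearly, axis=-1)
    annual[:, excluded] = np.nan
    return AnnualTwsa(basin_ids=twsa.basin_ids, annual=annual,
                      years=twsa.years,
                      excluded_years=twsa.years[excluded])
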