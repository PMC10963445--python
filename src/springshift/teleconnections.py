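"""Correlation maps of winter circulation indices against spring temperature.

Each grid cell's seasonal-mean series is rank-correlated (Spearman) with an
annual circulation-index series over their overlapping years, producing a
map of rho with a two-sided significance mask.  For short overlaps
(n <= 10) the p-value is exact, from the permutation distribution of the
rank statistic; longer overlaps use the t approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice, permutations

import numpy as np
import xarray as xr
from scipy import stats

from .io_formats import AnnualSeries

__all__ = ["CorrelationMap", "spearman", "correlation_map"]

_EXACT_N_MAX = 10


@dataclass
class CorrelationMap:
    lats: np.ndarray
    lons: np.ndarray
    r: np.ndarray
    p: np.ndarray
    sig_mask: np.ndarray
    n_years: int
    level: float


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact p from the permutation distribution of |rho|."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    n_hits = 0
    n_total = 0
    perm_iter = permutations(ry_c)
    while True:
        chunk = np.array(list(islice(perm_iter, 200_000)))
        if chunk.size == 0:
            break
        rhos = (chunk @ rx_c) / denom
        n_hits += int(np.sum(np.abs(rhos) >= abs(rho) - 1e-12))
        n_total += chunk.shape[0]
    return n_hits / n_total


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p (exact for n <= 10 without heavy cost)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two aligned samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    if x.size <= _EXACT_N_MAX:
        p = _exact_spearman_p(x, y, rho)
    return float(rho), float(p)


def _detrend(v: np.ndarray, t: np.ndarray) -> np.ndarray:
    b, a = np.polyfit(t, v, 1)
    return v - (b * t + a)


def correlation_map(index_annual: AnnualSeries, seasonal: xr.DataArray,
                    level: float = 0.95, detrend: bool = False,
                    min_overlap: int = 10) -> CorrelationMap:
    """Cell-wise Spearman correlation of a seasonal grid with an annual index.

    ``seasonal`` must have dims (year, lat, lon) — see
    :meth:`springshift.io_formats.MonthlyGrid.seasonal_mean`.  Cells with a
    constant series are left missing.  The mask flags p <= 1 - level.
    """
    if tuple(seasonal.dims) != ("year", "lat", "lon"):
        raise ValueError("expected dims (year, lat, lon)")
    idx = index_annual.dropna()
    gyears = seasonal["year"].values.astype(int)
    common, ii, ig = np.intersect1d(idx.years, gyears, return_indices=True)
    if common.size == 0:
        raise ValueError("index and grid share no years")
    if common.size < min_overlap:
        raise ValueError(f"overlap {common.size} < required {min_overlap} years")
    xv = idx.values[ii]
    if detrend:
        xv = _detrend(xv, common.astype(float))
    lats = seasonal["lat"].values
    lons = seasonal["lon"].values
    r = np.full((lats.size, lons.size), np.nan)
    p = np.full_like(r, np.nan)
    vals = seasonal.values[ig]
    for i in range(lats.size):
        for j in range(lons.size):
            cell = vals[:, i, j]
            if not np.all(np.isfinite(cell)) or np.ptp(cell) == 0:
                continue
            cv = _detrend(cell, common.astype(float)) if detrend else cell
            r[i, j], p[i, j] = spearman(xv, cv)
    mask = np.where(np.isfinite(p), p <= (1.0 - level), False)
    return CorrelationMap(lats, lons, r, p, mask, int(common.size), level)
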