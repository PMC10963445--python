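"""Trend, control-run resampling, and pre/post-regime change statistics.

Compares station, gridded and climate-model spring-temperature series: OLS
decadal trends and total warming over a common period, resampling of a long
pre-industrial control run into fixed-length segments to characterise
internal variability, and mean/variance comparisons across a regime break
(default 1976: the pre window includes 1976, the post window starts 1977).
Monotone-trend significance uses the Mann-Kendall test; variance change
uses a two-sided F test with the pre/post variance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy import stats

from .io_formats import AnnualSeries

__all__ = [
    "TrendResult",
    "ResampleSummary",
    "RegimeChangeSummary",
    "ChangeMaps",
    "decadal_trend",
    "resample_control",
    "pre_post_comparison",
    "mann_kendall",
    "change_maps",
]


@dataclass
class TrendResult:
    slope: float          # degC per decade
    intercept: float      # degC at year 0 of the fit
    period: tuple[int, int]
    total_change: float   # slope x span/10, degC over the period

    def __post_init__(self) -> None:
        span = self.period[1] - self.period[0]
        expected = self.slope * span / 10.0
        if not np.isclose(self.total_change, expected, atol=1e-9):
            raise ValueError("total_change inconsistent with slope and period")


@dataclass
class ResampleSummary:
    n_segments: int
    segment_length: int
    means: np.ndarray
    sds: np.ndarray
    trends: np.ndarray    # degC/decade per segment
    seed: int


@dataclass
class RegimeChangeSummary:
    break_year: int
    pre_mean: float
    post_mean: float
    pre_var: float
    post_var: float
    mk_tau: float
    mk_p: float
    f_stat: float
    f_p: float


@dataclass
class ChangeMaps:
    """Cell-wise pre/post change layers on the grid's (lat, lon) shape."""

    lats: np.ndarray
    lons: np.ndarray
    delta_mean: np.ndarray       # post minus pre, degC
    variance_change: np.ndarray  # post minus pre, degC^2
    mk_p: np.ndarray
    f_p: np.ndarray


def decadal_trend(series: AnnualSeries, period: tuple[int, int] = (1961, 2010)) -> TrendResult:
    """OLS trend of value on year over *period*, in degC per decade.

    ``total_change`` is slope x (end - start)/10 — e.g. 4.9 decades for
    1961-2010 — so the per-decade trend and the total are mutually
    consistent.
    """
    sub = series.window(*period).dropna()
    if len(sub) < 10:
        raise ValueError(f"need >= 10 non-missing years in {period}, got {len(sub)}")
    slope_yr, intercept = np.polyfit(sub.years, sub.values, 1)
    slope = slope_yr * 10.0
    span = period[1] - period[0]
    return TrendResult(slope, float(intercept), period, slope * span / 10.0)


def resample_control(series: AnnualSeries, n_segments: int = 100,
                     segment_length: int = 50, seed: int = 0) -> ResampleSummary:
    """Resample contiguous segments from a long control run.

    Start years are drawn uniformly with replacement over all admissible
    positions; per-segment mean, standard deviation and decadal trend are
    recorded, characterising unforced variability at the analysis window
    length.
    """
    x = series.dropna()
    n = len(x)
    if n < segment_length:
        raise ValueError(f"series length {n} shorter than segment length {segment_length}")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, n - segment_length + 1, size=n_segments)
    t = np.arange(segment_length)
    means = np.empty(n_segments)
    sds = np.empty(n_segments)
    trends = np.empty(n_segments)
    for i, s in enumerate(starts):
        seg = x.values[s:s + segment_length]
        means[i] = seg.mean()
        sds[i] = seg.std(ddof=1)
        trends[i] = np.polyfit(t, seg, 1)[0] * 10.0
    return ResampleSummary(n_segments, segment_length, means, sds, trends, seed)


def mann_kendall(values: np.ndarray | AnnualSeries) -> tuple[float, float]:
    """Mann-Kendall monotone-trend test: Kendall's tau of value against time.

    Uses the tie-corrected statistic with an exact p-value for short
    tie-free series and the normal approximation otherwise.  An all-equal
    series returns (0, 1).
    """
    x = values.dropna().values if isinstance(values, AnnualSeries) else np.asarray(values, float)
    if x.size < 4:
        raise ValueError("Mann-Kendall requires n >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("Mann-Kendall input must not contain missing values")
    if np.all(x == x[0]):
        return 0.0, 1.0
    res = stats.kendalltau(np.arange(x.size), x)
    return float(res.statistic), float(res.pvalue)


def pre_post_comparison(series: AnnualSeries, break_year: int = 1976) -> RegimeChangeSummary:
    """Mean/variance change across the break, with MK and F significance.

    The pre window runs through *break_year* inclusive; post starts the
    following year.  The F statistic is the pre/post sample-variance ratio
    with a two-sided p-value.
    """
    s = series.dropna()
    pre = s.values[s.years <= break_year]
    post = s.values[s.years > break_year]
    if pre.size < 3 or post.size < 3:
        raise ValueError("need >= 3 years on each side of the break")
    pre_var = float(np.var(pre, ddof=1))
    post_var = float(np.var(post, ddof=1))
    tau, mk_p = mann_kendall(s.values)
    f = pre_var / post_var
    dfn, dfd = pre.size - 1, post.size - 1
    cdf = stats.f.cdf(f, dfn, dfd)
    f_p = float(2.0 * min(cdf, 1.0 - cdf))
    return RegimeChangeSummary(break_year, float(pre.mean()), float(post.mean()),
                               pre_var, post_var, tau, mk_p, f, f_p)


def change_maps(seasonal: xr.DataArray, break_year: int = 1976) -> ChangeMaps:
    """Apply :func:`pre_post_comparison` to every cell of a (year, lat, lon) field."""
    if tuple(seasonal.dims) != ("year", "lat", "lon"):
        raise ValueError("expected dims (year, lat, lon); compute seasonal means first")
    years = seasonal["year"].values.astype(int)
    lats = seasonal["lat"].values
    lons = seasonal["lon"].values
    shape = (lats.size, lons.size)
    delta_mean = np.full(shape, np.nan)
    var_change = np.full(shape, np.nan)
    mk_p = np.full(shape, np.nan)
    f_p = np.full(shape, np.nan)
    vals = seasonal.values
    for i in range(shape[0]):
        for j in range(shape[1]):
            cell = vals[:, i, j]
            m = np.isfinite(cell)
            if m.sum() < 6:
                continue
            sub = AnnualSeries("cell", years[m], cell[m])
            try:
                r = pre_post_comparison(sub, break_year)
            except ValueError:
                continue
            delta_mean[i, j] = r.post_mean - r.pre_mean
            var_change[i, j] = r.post_var - r.pre_var
            mk_p[i, j] = r.mk_p
            f_p[i, j] = r.f_p
    return ChangeMaps(lats, lons, delta_mean, var_change, mk_p, f_p)
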