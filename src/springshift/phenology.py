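"""Harmonic NDVI modeling, green-up dates, and temperature-sensitivity maps.

Each pixel-year NDVI trajectory over Julian days 1-212 (January through the
end of July) is fitted with a first-order harmonic,

    ndvi(t) = a0 + a1 cos(2 pi t / 365) + b1 sin(2 pi t / 365),

by ordinary least squares, ignoring cloud-masked (missing) observations.
The start of spring is the day the fitted curve first crosses, while
rising, the 50% threshold between its minimum and maximum on the window:

    ndvi50 = ndvi_min + 0.5 (ndvi_max - ndvi_min).

Green-up dates are then regressed on spring (MAM) mean temperature per
pixel: the Pearson correlation r and the slope alpha (days per degC;
negative = earlier green-up when warmer) form the sensitivity map, which is
summarised by forest cover class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .io_formats import AnnualSeries

__all__ = [
    "HarmonicFit",
    "PhenoDate",
    "SensitivityResult",
    "fit_harmonic",
    "ndvi50_date",
    "pixel_sensitivity",
    "sensitivity_map",
    "classify_and_summarize",
    "DAY_WINDOW",
]

#: Julian-day fitting window: January 1 through the end of July.
DAY_WINDOW = (1, 212)
#: Continuous-time window for curve extrema and crossings: t = 0 is the
#: start of January 1, t = 212 the end of July 31.
EVAL_WINDOW = (0.0, 212.0)
_OMEGA = 2.0 * np.pi / 365.0


@dataclass
class HarmonicFit:
    pixel_id: str
    year: int
    a0: float
    a1: float
    b1: float
    fitted_min: float
    fitted_max: float
    rmse: float
    n_obs: int

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.a1, self.b1))

    @property
    def phase(self) -> float:
        return float(np.arctan2(self.b1, self.a1))

    def curve(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, float)
        return self.a0 + self.a1 * np.cos(_OMEGA * t) + self.b1 * np.sin(_OMEGA * t)


@dataclass
class PhenoDate:
    pixel_id: str
    year: int
    ndvi50: float
    sos_day: float        # continuous day of year of the rising 50% crossing
    ambiguous: bool = False


@dataclass
class SensitivityResult:
    pixel_id: str
    r: float
    alpha: float          # days per degC
    n_years: int


def fit_harmonic(days: np.ndarray, ndvi: np.ndarray, pixel_id: str = "",
                 year: int = 0) -> HarmonicFit:
    """Least-squares first-order harmonic over the day window.

    Requires >= 8 non-missing observations spanning >= 120 days within
    days 1-212.  The fitted extrema are those of the fitted curve evaluated
    on the window, not of the raw observations.
    """
    days = np.asarray(days, float)
    ndvi = np.asarray(ndvi, float)
    m = np.isfinite(ndvi) & (days >= DAY_WINDOW[0]) & (days <= DAY_WINDOW[1])
    d, v = days[m], ndvi[m]
    if d.size < 8:
        raise ValueError(f"pixel {pixel_id!r} year {year}: "
                         f"only {d.size} valid observations (need >= 8)")
    if np.ptp(d) < 120:
        raise ValueError(f"pixel {pixel_id!r} year {year}: observations span "
                         f"{np.ptp(d):.0f} days (need >= 120)")
    X = np.column_stack([np.ones_like(d), np.cos(_OMEGA * d), np.sin(_OMEGA * d)])
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    a0, a1, b1 = (float(c) for c in coef)
    resid = v - X @ coef
    rmse = float(np.sqrt(np.mean(resid ** 2)))

    lo, hi = _window_extrema(a0, a1, b1)
    return HarmonicFit(pixel_id, year, a0, a1, b1, lo, hi, rmse, int(d.size))


def _window_extrema(a0: float, a1: float, b1: float) -> tuple[float, float]:
    """Min and max of the fitted curve on the evaluation window (closed form)."""
    A = np.hypot(a1, b1)
    if A == 0:
        return a0, a0
    phi = np.arctan2(b1, a1)
    # stationary points where omega t - phi = k pi
    cands = [EVAL_WINDOW[0], EVAL_WINDOW[1]]
    k = 0
    while True:
        t = (phi + k * np.pi) / _OMEGA
        if t > EVAL_WINDOW[1]:
            break
        if t >= EVAL_WINDOW[0]:
            cands.append(t)
        k += 1
    vals = [a0 + A * np.cos(_OMEGA * t - phi) for t in cands]
    return float(min(vals)), float(max(vals))


def ndvi50_date(fit: HarmonicFit) -> PhenoDate:
    """The day the fitted curve first crosses its 50% threshold while rising.

    Solved in closed form for the single harmonic.  When no rising crossing
    exists inside the window (the fitted minimum falls after the maximum),
    the pixel-year is flagged ambiguous rather than silently dated.
    """
    if fit.amplitude <= 0:
        raise ValueError("flat harmonic fit: green-up date undefined")
    c = fit.fitted_min + 0.5 * (fit.fitted_max - fit.fitted_min)
    A, phi = fit.amplitude, fit.phase
    u = np.clip((c - fit.a0) / A, -1.0, 1.0)
    # curve = a0 + A cos(omega t - phi); rising where sin(omega t - phi) < 0,
    # i.e. the branch omega t - phi = -arccos(u) + 2 pi k
    base = -np.arccos(u)
    t = None
    for k in range(0, 3):
        cand = (phi + base + 2.0 * np.pi * k) / _OMEGA
        if EVAL_WINDOW[0] - 1e-9 <= cand <= EVAL_WINDOW[1] + 1e-9:
            t = float(np.clip(cand, *EVAL_WINDOW))
            break
        if cand > EVAL_WINDOW[1]:
            break
    if t is None:
        return PhenoDate(fit.pixel_id, fit.year, float(c), np.nan, ambiguous=True)
    return PhenoDate(fit.pixel_id, fit.year, float(c), t)


def pixel_sensitivity(dates: list[PhenoDate], temp: AnnualSeries,
                      min_years: int = 5) -> SensitivityResult:
    """Pearson r and OLS slope of green-up day on MAM temperature."""
    ok = [d for d in dates if not d.ambiguous and np.isfinite(d.sos_day)]
    if not ok:
        raise ValueError("no dated pixel-years")
    dyears = np.array([d.year for d in ok])
    sos = np.array([d.sos_day for d in ok])
    tv = temp.dropna()
    common, i1, i2 = np.intersect1d(dyears, tv.years, return_indices=True)
    if common.size < min_years:
        raise ValueError(f"only {common.size} overlapping years (need >= {min_years})")
    y, x = sos[i1], tv.values[i2]
    if np.ptp(x) == 0:
        raise ValueError("constant temperature: sensitivity undefined")
    if np.ptp(y) == 0:
        r = 0.0
    else:
        r = float(pearsonr(x, y).statistic)
    alpha = float(np.polyfit(x, y, 1)[0])
    return SensitivityResult(ok[0].pixel_id, r, alpha, int(common.size))


def sensitivity_map(dates_by_pixel: dict[str, list[PhenoDate]], temp: AnnualSeries,
                    min_years: int = 5) -> pd.DataFrame:
    """Per-pixel sensitivity table with columns pixel_id, r, alpha, n_years."""
    rows = []
    for pid, dates in dates_by_pixel.items():
        try:
            s = pixel_sensitivity(dates, temp, min_years)
        except ValueError:
            continue
        rows.append({"pixel_id": pid, "r": s.r, "alpha": s.alpha, "n_years": s.n_years})
    return pd.DataFrame(rows, columns=["pixel_id", "r", "alpha", "n_years"])


#: The four aggregated forest cover categories of the study region.
COVER_CLASSES = ("upland conifer", "lowland conifer", "oak savannah", "upland deciduous")


def classify_and_summarize(sens: pd.DataFrame,
                           cover: dict[str, str] | pd.Series) -> pd.DataFrame:
    """Summarise per-pixel sensitivity by forest cover class.

    ``cover`` maps pixel_id -> class label (a co-registered categorical
    raster flattened to pixel ids).  Pixels without a class are excluded
    and counted under the ``unclassified`` row; classes with no pixels are
    reported with n = 0.
    """
    cover = pd.Series(cover)
    df = sens.copy()
    df["cover_class"] = df["pixel_id"].map(cover)
    classes = list(pd.unique(cover.dropna()))
    rows = []
    for cls in classes:
        grp = df[df["cover_class"] == cls]
        rows.append(_class_row(cls, grp))
    n_unclassified = int(df["cover_class"].isna().sum())
    out = pd.DataFrame(rows)
    out.attrs["n_unclassified"] = n_unclassified
    return out


def _class_row(cls: str, grp: pd.DataFrame) -> dict:
    if grp.empty:
        return {"cover_class": cls, "n": 0, "r_mean": np.nan, "r_q25": np.nan,
                "r_median": np.nan, "r_q75": np.nan, "alpha_mean": np.nan,
                "alpha_q25": np.nan, "alpha_median": np.nan, "alpha_q75": np.nan}
    return {
        "cover_class": cls,
        "n": int(len(grp)),
        "r_mean": grp["r"].mean(),
        "r_q25": grp["r"].quantile(0.25),
        "r_median": grp["r"].median(),
        "r_q75": grp["r"].quantile(0.75),
        "alpha_mean": grp["alpha"].mean(),
        "alpha_q25": grp["alpha"].quantile(0.25),
        "alpha_median": grp["alpha"].median(),
        "alpha_q75": grp["alpha"].quantile(0.75),
    }
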