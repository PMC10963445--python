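"""Readers/writers for the standard formats the pipeline touches.

The exchange types here are deliberately lightweight: every analysis stage
consumes and produces :class:`AnnualSeries` (one value per calendar year),
so station records, gridded fields, circulation indices and ring widths all
funnel through the calendar/season aggregation helpers in this module.

Supported on-disk formats:

* Tucson (decadal) RWL ring-width files, the deposition standard of the
  International Tree-Ring Databank.
* CSV station tables with columns ``date, tmax, tmin, tmean``.
* Whitespace/CSV monthly circulation-index tables ``year, month, value``.
* CF-style NetCDF (classic, via the scipy backend) for monthly grids.
* CSV for all :class:`AnnualSeries` exports, with ``NA`` as the missing
  sentinel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "DailySeries",
    "MonthlyGrid",
    "AnnualSeries",
    "IndexSeries",
    "RingSeries",
    "RWLParseError",
    "read_rwl",
    "write_rwl",
    "read_station_csv",
    "read_index_table",
    "seasonal_mean",
    "winter_mean_index",
    "MAM",
    "DJFM",
]

#: March–April–May, the spring season used throughout the analysis.
MAM = (3, 4, 5)
#: December(previous year)–March, the winter window for circulation indices.
DJFM = (12, 1, 2, 3)

_NA = "NA"


# ---------------------------------------------------------------------------
# Exchange types
# ---------------------------------------------------------------------------


@dataclass
class AnnualSeries:
    """One value per calendar year — the universal exchange type.

    Missing values are NaN.  ``years`` must be strictly increasing.
    """

    site_id: str
    years: np.ndarray
    values: np.ndarray
    season_label: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape:
            raise ValueError("years and values must have the same length")
        if self.years.size and np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")

    def __len__(self) -> int:
        return self.years.size

    def dropna(self) -> "AnnualSeries":
        m = np.isfinite(self.values)
        return AnnualSeries(self.site_id, self.years[m], self.values[m], self.season_label)

    def align(self, other: "AnnualSeries") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Intersect years with *other*; returns (years, self values, other values)."""
        a, b = self.dropna(), other.dropna()
        years, ia, ib = np.intersect1d(a.years, b.years, return_indices=True)
        return years, a.values[ia], b.values[ib]

    def window(self, start: int, end: int) -> "AnnualSeries":
        m = (self.years >= start) & (self.years <= end)
        return AnnualSeries(self.site_id, self.years[m], self.values[m], self.season_label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "value": self.values})

    def write_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.to_csv(path, index=False, na_rep=_NA, float_format="%.6f")

    @classmethod
    def read_csv(cls, path: str | Path, site_id: str = "", season_label: str = "") -> "AnnualSeries":
        df = pd.read_csv(path, na_values=[_NA])
        return cls(site_id or Path(path).stem, df["year"].to_numpy(int),
                   df["value"].to_numpy(float), season_label)


@dataclass
class DailySeries:
    """A daily station temperature record; missing values are NaN."""

    site_id: str
    dates: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values must have the same length")
        if len(self.dates) > 1:
            diffs = np.diff(self.dates.values)
            if np.any(diffs <= np.timedelta64(0, "ns")):
                raise ValueError("dates must be strictly increasing with no duplicates")

    def __len__(self) -> int:
        return len(self.dates)


@dataclass
class IndexSeries:
    """A monthly standardized circulation index (PNA, NAM, ...)."""

    name: str
    years: np.ndarray
    months: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.months = np.asarray(self.months, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.years.shape == self.months.shape == self.values.shape):
            raise ValueError("years, months, values must have equal length")
        key = self.years * 12 + (self.months - 1)
        if len(np.unique(key)) != len(key):
            raise ValueError("duplicate (year, month) entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "month": self.months, "value": self.values})

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep=_NA)


@dataclass
class RingSeries:
    """Ring widths for a single increment core, in millimetres."""

    series_id: str
    first_year: int
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.size < 1:
            raise ValueError("ring series must contain at least one width")
        if np.any(self.widths < 0):
            raise ValueError("ring widths must be non-negative")

    @property
    def years(self) -> np.ndarray:
        return self.first_year + np.arange(self.widths.size)

    @property
    def last_year(self) -> int:
        return self.first_year + self.widths.size - 1


@dataclass
class MonthlyGrid:
    """A regular lat/lon grid of monthly temperature, wrapping an xarray DataArray.

    Dimensions are ``(time, lat, lon)`` with monthly timestamps; 0.5-degree
    cell centres follow the CRU grid convention when built from the study
    region.
    """

    data: xr.DataArray = field(repr=False)

    def __post_init__(self) -> None:
        if tuple(self.data.dims) != ("time", "lat", "lon"):
            raise ValueError("MonthlyGrid requires dims (time, lat, lon)")

    @property
    def lats(self) -> np.ndarray:
        return self.data["lat"].values

    @property
    def lons(self) -> np.ndarray:
        return self.data["lon"].values

    @classmethod
    def from_arrays(cls, years: Sequence[int], months: Sequence[int],
                    lats: Sequence[float], lons: Sequence[float],
                    values: np.ndarray, name: str = "temperature") -> "MonthlyGrid":
        times = pd.to_datetime([f"{y}-{m:02d}-01" for y, m in zip(years, months)])
        da = xr.DataArray(
            np.asarray(values, dtype=float),
            coords={"time": times, "lat": np.asarray(lats, float), "lon": np.asarray(lons, float)},
            dims=("time", "lat", "lon"),
            name=name,
            attrs={"units": "degC"},
        )
        return cls(da)

    def seasonal_mean(self, months: Iterable[int] = MAM) -> xr.DataArray:
        """Per-cell unweighted mean of the listed months, one slice per year.

        Years in which any listed month is absent are dropped.
        """
        months = sorted(set(int(m) for m in months))
        da = self.data.sel(time=self.data["time"].dt.month.isin(months))
        grouped = da.groupby(da["time"].dt.year).mean("time")
        counts = da.groupby(da["time"].dt.year).count("time")
        complete = (counts >= len(months)).all(["lat", "lon"])
        out = grouped.where(complete, drop=True).rename(year="year")
        return out

    def to_netcdf(self, path: str | Path) -> None:
        self.data.to_dataset(name=self.data.name or "temperature").to_netcdf(
            path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path, var: str | None = None) -> "MonthlyGrid":
        ds = xr.open_dataset(path, engine="scipy")
        name = var or list(ds.data_vars)[0]
        return cls(ds[name].transpose("time", "lat", "lon").load())


# ---------------------------------------------------------------------------
# Tucson RWL ring-width format
# ---------------------------------------------------------------------------


class RWLParseError(ValueError):
    """Raised for malformed Tucson-format input, naming the offending line."""


def _rwl_precision(stop_marker: int) -> float:
    # 999 terminates 0.01 mm files, -9999 terminates 0.001 mm files
    return 0.01 if stop_marker == 999 else 0.001


def read_rwl(path: str | Path) -> list[RingSeries]:
    """Read a Tucson decadal-format ring-width file.

    Both common dialects are handled: widths in 0.01 mm terminated by
    ``999`` and widths in 0.001 mm terminated by ``-9999``.  Widths are
    returned in millimetres.
    """
    # group consecutive rows by series id first: only then can a trailing
    # 999 be told apart from a data value of 999 (= 0.999 mm) inside a
    # 0.001 mm file terminated by -9999
    groups: list[tuple[str, int, list[tuple[int, int, list[int]]]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            sid = raw[:8].strip()
            rest = raw[8:].split()
            if not sid or len(rest) < 2:
                raise RWLParseError(f"line {lineno}: malformed decade row")
            try:
                year = int(rest[0])
                vals = [int(v) for v in rest[1:]]
            except ValueError as exc:
                raise RWLParseError(f"line {lineno}: non-numeric field") from exc
            if groups and groups[-1][0] == sid:
                groups[-1][2].append((lineno, year, vals))
            else:
                groups.append((sid, lineno, [(lineno, year, vals)]))

    seen: set[str] = set()
    out: list[RingSeries] = []
    for sid, first_line, rows in groups:
        if sid in seen:
            raise RWLParseError(f"line {first_line}: duplicate series id {sid!r}")
        seen.add(sid)
        first_year = rows[0][1]
        flat: list[int] = []
        n_so_far = 0
        for lineno, year, vals in rows:
            if n_so_far > 0:
                expected = ((first_year + n_so_far - 1) // 10 + 1) * 10
                if year != expected:
                    raise RWLParseError(
                        f"line {lineno}: decade row starts at {year}, "
                        f"expected {expected}")
            flat.extend(vals)
            n_so_far = len(flat)
        if not flat:
            raise RWLParseError(f"series {sid!r} is empty")
        stop = flat[-1]
        if stop == -9999:
            scale = _rwl_precision(stop)
        elif 999 in flat:
            scale = _rwl_precision(999)
            flat = flat[: flat.index(999) + 1]
            stop = 999
        else:
            raise RWLParseError(f"series {sid!r} missing stop marker")
        widths = [v * scale for v in flat[:-1]]
        if not widths:
            raise RWLParseError(f"series {sid!r} has no ring widths")
        out.append(RingSeries(sid, first_year, np.asarray(widths)))
    return out


def write_rwl(series_set: Iterable[RingSeries], path: str | Path,
              precision: float = 0.001) -> None:
    """Write ring series in Tucson decadal format.

    Widths are stored as integer units of *precision* millimetres
    (default 0.001 mm, terminated by ``-9999``); values that are not exact
    multiples of the precision are rounded with a warning.
    """
    if precision not in (0.01, 0.001):
        raise ValueError("precision must be 0.01 or 0.001 mm")
    stop = 999 if precision == 0.01 else -9999
    width_fmt = 6
    lines: list[str] = []
    for s in series_set:
        if len(s.series_id) > 8:
            raise ValueError(f"series id {s.series_id!r} exceeds 8 characters")
        ints = s.widths / precision
        rounded = np.rint(ints)
        if not np.allclose(ints, rounded, atol=1e-6):
            warnings.warn(
                f"series {s.series_id!r}: widths rounded to {precision} mm precision")
        ints = rounded.astype(int)
        year = s.first_year
        i = 0
        vals = list(ints) + [stop]
        while i < len(vals):
            decade_end = (year // 10 + 1) * 10
            n = min(decade_end - year, len(vals) - i)
            chunk = vals[i:i + n]
            body = "".join(f"{v:>{width_fmt}d}" for v in chunk)
            lines.append(f"{s.series_id:<8s}{year:>4d}{body}")
            i += n
            year = decade_end
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Station and index tables
# ---------------------------------------------------------------------------


def read_station_csv(path: str | Path, site_id: str = "",
                     variable: str = "tmean") -> DailySeries:
    """Read a daily station table with columns ``date, tmax, tmin[, tmean]``.

    When ``tmean`` is requested but absent it is derived as
    ``(tmax + tmin) / 2``, the GHCN-daily convention.
    """
    df = pd.read_csv(path, na_values=[_NA])
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values("date")
    if variable == "tmean" and "tmean" not in df.columns:
        vals = (df["tmax"].to_numpy(float) + df["tmin"].to_numpy(float)) / 2.0
    else:
        vals = df[variable].to_numpy(float)
    return DailySeries(site_id or Path(path).stem, pd.DatetimeIndex(df["date"]), vals)


def read_index_table(path: str | Path, name: str = "") -> IndexSeries:
    """Read a monthly index table (CSV or whitespace) with year, month, value."""
    try:
        df = pd.read_csv(path, na_values=[_NA])
        if df.shape[1] < 3:
            raise ValueError
    except ValueError:
        df = pd.read_csv(path, sep=r"\s+", na_values=[_NA])
    df.columns = [c.lower() for c in df.columns]
    return IndexSeries(name or Path(path).stem, df["year"].to_numpy(int),
                       df["month"].to_numpy(int), df["value"].to_numpy(float))


# ---------------------------------------------------------------------------
# Calendar / season aggregation
# ---------------------------------------------------------------------------


def _days_in_months(year: int, months: Sequence[int]) -> int:
    return int(sum(pd.Period(f"{year}-{m:02d}").days_in_month for m in months))


def seasonal_mean(series: DailySeries | pd.DataFrame, months: Iterable[int] = MAM,
                  min_coverage: float = 0.9) -> AnnualSeries:
    """Seasonal mean per calendar year.

    For a :class:`DailySeries` the mean is day-weighted over all days of the
    listed months; a year is missing when fewer than ``min_coverage`` of its
    season days carry valid values.  For a monthly DataFrame (columns
    ``year, month, value``) the mean is the unweighted mean of the monthly
    values, with coverage counted in months.
    """
    months = sorted(set(int(m) for m in months))
    if not months or any(m < 1 or m > 12 for m in months):
        raise ValueError("months must be a non-empty subset of 1..12")
    label = "".join("JFMAMJJASOND"[m - 1] for m in months)

    if isinstance(series, DailySeries):
        if len(series) == 0:
            return AnnualSeries(series.site_id, np.array([], int), np.array([]), label)
        df = pd.DataFrame({"year": series.dates.year, "month": series.dates.month,
                           "value": series.values})
        df = df[df["month"].isin(months)]
        years, values = [], []
        for year, grp in df.groupby("year"):
            n_expected = _days_in_months(int(year), months)
            n_valid = int(grp["value"].notna().sum())
            years.append(int(year))
            values.append(grp["value"].mean() if n_valid >= min_coverage * n_expected
                          else np.nan)
        return AnnualSeries(series.site_id, np.array(years), np.array(values), label)

    df = pd.DataFrame(series)
    if df.empty:
        return AnnualSeries("", np.array([], int), np.array([]), label)
    df = df[df["month"].isin(months)]
    years, values = [], []
    for year, grp in df.groupby("year"):
        n_valid = int(grp["value"].notna().sum())
        years.append(int(year))
        values.append(grp["value"].mean() if n_valid >= min_coverage * len(months)
                      else np.nan)
    return AnnualSeries("", np.array(years), np.array(values), label)


def winter_mean_index(index: IndexSeries) -> AnnualSeries:
    """DJFM winter mean of a monthly index, labeled by the January year.

    The value for year *y* is the mean of Dec(*y*−1), Jan(*y*), Feb(*y*),
    Mar(*y*); the first year with no preceding December is missing.
    """
    df = index.to_frame()
    df = df[df["month"].isin(DJFM)].copy()
    # December belongs to the following (January-labelled) winter year
    df["wyear"] = np.where(df["month"] == 12, df["year"] + 1, df["year"])
    years, values = [], []
    for wy, grp in df.groupby("wyear"):
        years.append(int(wy))
        values.append(grp["value"].mean() if len(grp) == 4 and grp["value"].notna().all()
                      else np.nan)
    return AnnualSeries(index.name, np.array(years), np.array(values), "DJFM")
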