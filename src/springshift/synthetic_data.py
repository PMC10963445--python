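"""Seeded generators emulating every input the analysis pipeline consumes.

The defaults encode the study conditions the pipeline is designed around:
annual spring temperature over 1911-2020 with an abrupt mean/variance shift
after 1976 (pre: mean 3.33 degC, variance 1.33; post: mean 4.60, variance
3.00) riding on AR(1) noise with lag-1 autocorrelation 0.2; a red-noise
monthly circulation index with an optional sustained positive phase;
ring-width series combining a negative-exponential age curve, a
time-varying climate coupling and disturbance releases, with two cores per
tree sharing the tree-level signal; NDVI seasonal curves whose green-up day
responds linearly to spring temperature at -3 days per degC; and a monthly
temperature grid whose cells load on the winter index with a configurable
spatial pattern.

Every generator is a pure function of its configuration (seed included),
so outputs are bit-reproducible.  AR(1) noise is parameterised by its
marginal (stationary) variance — the observable quantity — with the
innovation variance derived internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import AnnualSeries, IndexSeries, MonthlyGrid, RingSeries

__all__ = [
    "RegimeConfig",
    "RingConfig",
    "NDVIConfig",
    "GridConfig",
    "GeneratorConfig",
    "gen_spring_temperature",
    "gen_circulation_index",
    "gen_ring_series",
    "gen_ndvi_stack",
    "gen_monthly_grid",
]

# fixed substream tags so the per-generator streams are independent
_STREAMS = {"temperature": 1, "index": 2, "rings": 3, "ndvi": 4, "grid": 5}


@dataclass
class RegimeConfig:
    """The abrupt shift in spring-temperature statistics."""

    break_year: int = 1976
    pre_mean: float = 3.33    # degC
    pre_var: float = 1.33     # degC^2
    post_mean: float = 4.60
    post_var: float = 3.00

    def __post_init__(self) -> None:
        if self.pre_var <= 0 or self.post_var <= 0:
            raise ValueError("variances must be positive")


@dataclass
class RingConfig:
    n_trees: int = 15
    cores_per_tree: int = 2
    negexp_a: float = 1.5     # mm, initial excess growth
    negexp_b: float = 0.02    # per year
    negexp_c: float = 0.4     # mm, asymptotic width
    beta_start: float = 0.0   # climate coupling at the start of the record
    beta_end: float = 0.6     # ... ramping linearly to this at the end
    releases: tuple = ()      # (year, log-magnitude, duration) triples
    tree_noise_sd: float = 0.15
    core_noise_sd: float = 0.10
    max_age_offset: int = 30  # trees establish within this many years of start


@dataclass
class NDVIConfig:
    n_pixels: int = 200
    alpha_true: float = -3.0      # days of green-up advance per degC
    base_day: float = 100.0       # mean green-up day of year
    a0: float = 0.5               # seasonal mean NDVI
    amplitude: float = 0.25       # harmonic amplitude
    noise_sd: float = 0.02        # NDVI observation noise
    day_step: int = 8             # observation cadence in days
    missing_fraction: float = 0.2
    pixel_day_noise_sd: float = 2.0  # pixel-year jitter of the green-up day
    classes: tuple = ("upland conifer", "lowland conifer",
                      "oak savannah", "upland deciduous")
    class_alphas: tuple | None = None  # per-class alpha override

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")


@dataclass
class GridConfig:
    nlat: int = 5
    nlon: int = 5
    lat0: float = 40.25
    lon0: float = -96.75
    spacing: float = 0.5
    loading: str | np.ndarray = "gradient"  # per-cell loading on the index
    noise_sd: float = 0.8
    clim_annual_mean: float = 4.0
    clim_seasonal_amp: float = 14.0


@dataclass
class GeneratorConfig:
    seed: int = 0
    years: tuple[int, int] = (1911, 2020)
    regime: RegimeConfig = field(default_factory=RegimeConfig)
    trend: float = 0.0        # degC per decade, added on top of the step
    ar1: float = 0.2          # lag-1 autocorrelation of the annual noise
    index_ar1: float = 0.5    # lag-1 autocorrelation of the monthly index
    index_phase: tuple | None = (1977, 1988, 1.0)  # (start, end, offset) or None
    ring: RingConfig = field(default_factory=RingConfig)
    ndvi: NDVIConfig = field(default_factory=NDVIConfig)
    grid: GridConfig = field(default_factory=GridConfig)

    def __post_init__(self) -> None:
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError("ar1 must lie in (-1, 1)")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


def _ar1_unit(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) with unit marginal variance."""
    z = np.empty(n)
    z[0] = rng.normal()
    innov_sd = np.sqrt(1.0 - phi ** 2)
    eps = rng.normal(size=n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        z[t] = phi * z[t - 1] + innov_sd * eps[t - 1]
    return z


def gen_spring_temperature(cfg: GeneratorConfig) -> AnnualSeries:
    """Annual spring temperature: piecewise mean + trend + AR(1) noise.

    The noise has the configured marginal variance within each regime, so
    sample pre/post moments estimate the configured values directly.
    """
    y0, y1 = cfg.years
    years = np.arange(y0, y1 + 1)
    rng = cfg.rng("temperature")
    z = _ar1_unit(years.size, cfg.ar1, rng)
    post = years > cfg.regime.break_year
    mean = np.where(post, cfg.regime.post_mean, cfg.regime.pre_mean)
    sd = np.where(post, np.sqrt(cfg.regime.post_var), np.sqrt(cfg.regime.pre_var))
    values = mean + cfg.trend * (years - y0) / 10.0 + sd * z
    return AnnualSeries("synthetic", years, values, "MAM")


def gen_circulation_index(cfg: GeneratorConfig) -> IndexSeries:
    """Monthly red-noise circulation index, standardised, with optional phase.

    ``index_phase = (start, end, offset)`` adds a sustained positive excursion
    over the given winters, emulating a prolonged positive phase of the
    index.
    """
    y0, y1 = cfg.years
    years = np.repeat(np.arange(y0, y1 + 1), 12)
    months = np.tile(np.arange(1, 13), y1 - y0 + 1)
    rng = cfg.rng("index")
    z = _ar1_unit(years.size, cfg.index_ar1, rng)
    z = (z - z.mean()) / z.std()
    if cfg.index_phase is not None:
        start, end, offset = cfg.index_phase
        # winter year = January-labelled; December belongs to the next winter
        wyear = np.where(months == 12, years + 1, years)
        z = z + np.where((wyear >= start) & (wyear <= end), offset, 0.0)
    return IndexSeries("synthetic_index", years, months, z)


def _negexp_curve(age: np.ndarray, ring: RingConfig) -> np.ndarray:
    return ring.negexp_a * np.exp(-ring.negexp_b * age) + ring.negexp_c


def gen_ring_series(cfg: GeneratorConfig, climate: AnnualSeries) -> list[RingSeries]:
    """Ring-width cores: age curve x exp(climate signal + releases + noise).

    The climate coupling beta(t) ramps linearly from ``beta_start`` to
    ``beta_end`` over the record, multiplying the standardised climate
    anomaly.  Releases add a log-scale step for their duration.  Both cores
    of a tree share the tree-level signal and differ by core-level noise.
    """
    ring = cfg.ring
    clim = climate.dropna()
    z = (clim.values - clim.values.mean()) / clim.values.std()
    zmap = dict(zip(clim.years.tolist(), z))
    y0, y1 = int(clim.years[0]), int(clim.years[-1])
    rng = cfg.rng("rings")
    out: list[RingSeries] = []
    for tree in range(ring.n_trees):
        start = y0 + int(rng.integers(0, ring.max_age_offset + 1))
        years = np.arange(start, y1 + 1)
        frac = (years - y0) / max(y1 - y0, 1)
        beta = ring.beta_start + (ring.beta_end - ring.beta_start) * frac
        zc = np.array([zmap.get(int(y), 0.0) for y in years])
        release = np.zeros(years.size)
        for (ry, mag, dur) in ring.releases:
            release += np.where((years >= ry) & (years < ry + dur), mag, 0.0)
        tree_noise = rng.normal(0.0, ring.tree_noise_sd, years.size)
        log_signal = beta * zc + release + tree_noise
        age = years - start
        base = _negexp_curve(age.astype(float), ring)
        for core in range(ring.cores_per_tree):
            core_noise = rng.normal(0.0, ring.core_noise_sd, years.size)
            # measurement resolution: 0.001 mm, as produced by a stage micrometer
            widths = np.round(base * np.exp(log_signal + core_noise), 3)
            sid = f"T{tree + 1:02d}{chr(ord('A') + core)}"
            out.append(RingSeries(sid, start, widths))
    return out


def gen_ndvi_stack(cfg: GeneratorConfig, temp: AnnualSeries
                   ) -> tuple[dict[str, dict[int, tuple[np.ndarray, np.ndarray]]],
                              dict[str, str]]:
    """NDVI pixel stacks whose green-up day tracks spring temperature.

    Returns ``(stack, cover)``: ``stack[pixel_id][year] = (days, ndvi)``
    sampled every ``day_step`` days over the fitting window with
    observations removed at ``missing_fraction``, and a pixel -> cover
    class mapping.  The generating green-up day is
    ``base_day + alpha (T - mean T) + noise``; the curve places its rising
    50% crossing exactly there.
    """
    nd = cfg.ndvi
    tv = temp.dropna()
    t_anom = tv.values - tv.values.mean()
    rng = cfg.rng("ndvi")
    days_all = np.arange(1, 213, nd.day_step, dtype=float)
    omega = 2.0 * np.pi / 365.0

    classes = list(nd.classes)
    alphas = list(nd.class_alphas) if nd.class_alphas is not None else [
        nd.alpha_true] * len(classes)
    stack: dict[str, dict[int, tuple[np.ndarray, np.ndarray]]] = {}
    cover: dict[str, str] = {}
    for p in range(nd.n_pixels):
        pid = f"px{p:04d}"
        ci = p % len(classes)
        cover[pid] = classes[ci]
        alpha = alphas[ci]
        per_year: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for yi, year in enumerate(tv.years):
            d50 = (nd.base_day + alpha * t_anom[yi]
                   + rng.normal(0.0, nd.pixel_day_noise_sd))
            t_peak = d50 + 365.0 / 4.0
            curve = nd.a0 + nd.amplitude * np.cos(omega * (days_all - t_peak))
            ndvi = curve + rng.normal(0.0, nd.noise_sd, days_all.size)
            keep = rng.random(days_all.size) >= nd.missing_fraction
            per_year[int(year)] = (days_all[keep], np.clip(ndvi[keep], -1.0, 1.0))
        stack[pid] = per_year
    return stack, cover


def _loading_pattern(grid: GridConfig) -> np.ndarray:
    if isinstance(grid.loading, np.ndarray):
        if grid.loading.shape != (grid.nlat, grid.nlon):
            raise ValueError("loading array must match the grid shape")
        return grid.loading
    if grid.loading == "gradient":
        # loading decays west-to-east across the domain
        col = np.linspace(1.0, 0.0, grid.nlon)
        return np.tile(col, (grid.nlat, 1))
    if grid.loading == "zero":
        return np.zeros((grid.nlat, grid.nlon))
    raise ValueError(f"unknown loading pattern {grid.loading!r}")


def gen_monthly_grid(cfg: GeneratorConfig, index: IndexSeries) -> MonthlyGrid:
    """Monthly temperature grid: climatology + loading x winter index + noise."""
    from .io_formats import winter_mean_index

    g = cfg.grid
    widx = winter_mean_index(index).dropna()
    years = np.repeat(widx.years, 12)
    months = np.tile(np.arange(1, 13), widx.years.size)
    lats = g.lat0 + g.spacing * np.arange(g.nlat)
    lons = g.lon0 + g.spacing * np.arange(g.nlon)
    loading = _loading_pattern(g)
    rng = cfg.rng("grid")
    clim = (g.clim_annual_mean
            - g.clim_seasonal_amp / 2.0 * np.cos(2.0 * np.pi * (months - 1) / 12.0))
    idx_by_year = dict(zip(widx.years.tolist(), widx.values))
    vals = np.empty((years.size, g.nlat, g.nlon))
    for t in range(years.size):
        forced = loading * idx_by_year[int(years[t])]
        vals[t] = clim[t] + forced + rng.normal(0.0, g.noise_sd, (g.nlat, g.nlon))
    return MonthlyGrid.from_arrays(years, months, lats, lons, vals)
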