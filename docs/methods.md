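# Methods

This note records the statistical models implemented in `springshift`, the
defaults and numerical choices behind them, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Hidden Markov regime model

Annual observations (spring temperature in °C, or a dimensionless
ring-width index) are modelled as emissions from K hidden climate states,
Gaussian within each state: p(X_t | S_t=k) = N(μ_k, σ_k²). The state
sequence is Markov with a row-stochastic transition matrix. When covariates
are supplied (a forced-warming curve, a winter circulation index), each
transition row follows a multinomial logit with the row's own state as the
reference category:

    P(S_{t+1}=j | S_t=i, z_t) ∝ exp(a_ij + b_ij · z_t),    a_ii = b_ii = 0.

With all b = 0 the model reduces exactly to a homogeneous HMM, which the
tests verify as an identity. Covariates are standardised (zero mean, unit
sd) over the fitting window before entering the logit; coefficients are
reported on that scale. Covariate rows are aligned to the origin step of
each transition.

**Free-parameter count.** k = (K−1) initial + K(K−1)(1+p) transition +
2K emission; 7 for the two-state covariate-free model, 2 for the one-state
model. AIC = 2k − 2logL, BIC = k·lnT − 2logL.

**Fitting.** EM with the forward–backward recursions run in scaled linear
arithmetic (per-step normalised emission densities keep the computation
exact in log terms while avoiding per-step log-sum-exp calls). Emission
updates are closed-form weighted moments; transition updates are the count
ratio when p = 0 and a per-row weighted multinomial-logit maximisation
(BFGS with analytic gradients, warm-started, never accepted if it worsens
the expected complete-data log-likelihood) when p > 0. Initialisation is
deliberately conservative about state changes: initial probabilities
(0.95, 0.05, ...), sticky transitions (0.9 diagonal), emission means at
spread quantiles of the data, pooled-sd emission scales. Restarts (default
3) jitter the means by ±0.5 sd with a seeded generator, and the restart
with the highest log-likelihood wins. A variance floor of 1e−3 × pooled sd
prevents single-point spikes; because that constraint can break strict EM
ascent in a near-degenerate corner, a backward step larger than 1e−8 rolls
the fit back to the last good iterate rather than discarding the run. A
converged fit in which any state carries less than two observations of
posterior mass is rejected as degenerate; if every restart degenerates the
fit errors out. States are relabelled so state 0 has the lower emission
mean, making "cool → warm" transition semantics deterministic.

**Transition year.** The Viterbi path is summarised as a transition year
only when it switches state exactly once; the year reported is the last
year spent in the initial state. Paths that flicker between states yield
no transition year — a deliberate conservatism, since a single printed year
for an unstable decoding would overstate what the model found.

**Model comparison.** One-state vs two-state vs two-state-with-covariates,
by ΔAIC, ΔBIC and the likelihood-ratio statistic 2(ℓ_alt − ℓ_null) against
a χ² reference with df = Δk. The one-vs-two-state comparison sits on the
boundary of the parameter space where the χ² reference is not strictly
valid; the test is reported anyway (the conventional practice this package
follows), and the suite checks empirically that the resulting size on
one-state-generated data stays below 15% at nominal 5%. When covariates are
supplied, both the covariate model and the two-state model it is compared
against are refitted on the window where all covariates exist, because the
comparison is only meaningful on a common observation vector.

**Missing years** are not interpolated: series must be gap-free within a
fit, and callers split at gaps.

## Attribution statistics

- Decadal trend: OLS of value on year × 10, over a stated period (default
  1961–2010). Total change = slope × span/10 with span = end − start (4.9
  decades for 1961–2010), so printed trends and totals are mutually
  consistent.
- Control-run resampling: 100 segments of 50 years drawn uniformly with
  replacement from a long unforced control series; per-segment mean, sd and
  decadal trend characterise internal variability at the analysis window
  length.
- Pre/post comparison: the pre window includes the break year (default
  1976, so "post" starts with the anomalously warm 1977); sample means and
  variances per window, Mann–Kendall on the full series, and a two-sided F
  test on the pre/post variance ratio with (n_pre−1, n_post−1) df. Under a
  window swap the F statistic inverts and the two-sided p is unchanged.
- Mann–Kendall: Kendall's tau of value against time, tie-corrected, exact
  p for short tie-free series and the normal approximation otherwise. OLS
  supplies the trend magnitude; Mann–Kendall supplies its significance.

## Teleconnection maps

Winter (DJFM) index means are labelled by the January year — December 1976
belongs to winter 1977 — so the circulation covariate lines up with the
following spring. Correlation is Spearman's ρ per grid cell over the
overlap years (≥ 10 required), two-sided. For n ≤ 10 the p-value is exact,
computed from the full permutation distribution of the rank statistic
(enumerated in chunks to bound memory); beyond that the t approximation is
used. Cells with constant series are left missing rather than given a
spurious ρ. A `detrend` flag (default off) removes OLS linear trends from
both sides before correlating, for separating interannual covariation from
shared trend. No field-significance or false-discovery adjustment is
applied to the map.

## Dendrochronology

Two standardisation options, chosen per site:

- Modified negative exponential w(t) = a·e^(−bt) + c with a, b > 0, c ≥ 0,
  fitted by bounded least squares. If the fit fails or the curve is
  effectively flat/non-decreasing, the series mean is used instead and the
  fallback is flagged — growth releases from stand-wide disturbance make
  the negative exponential inappropriate for many series.
- A smoothing spline implemented as a second-difference penalised smoother
  with penalty λ = 1/(16·sin⁴(π/λ_w)), which gives a 50% frequency response
  at the chosen wavelength λ_w (default 100 years). It reproduces straight
  lines exactly and, as verified in the tests, attenuates a 100-year
  sinusoid to 50% ± 5% amplitude while passing a 10-year cycle essentially
  untouched into the index.

The index is width / fitted curve. Chronologies are per-year arithmetic
means of core indices (a robust averaging variant is deliberately not the
default). RBAR is the mean pairwise Pearson correlation between cores over
each pair's own overlap (pairs sharing fewer than 3 years are skipped);
EPS = n̄·rbar/(n̄·rbar + 1 − rbar) with n̄ the mean sample depth, with the
conventional 0.85 adequacy cutoff exposed as a flag.

Running climate–growth correlations use a 10-year sliding window, step 1
(a step of 10 gives true decadal bins). Significance of the trend in the
correlation series comes from a block bootstrap: the climate series is
resampled in contiguous 10-year blocks with replacement (preserving
autocorrelation, breaking the pairing with growth; the last partial block
is retained), running correlations are recomputed per iteration (default
1000), and the null threshold is the 90% quantile of |r| under that null.
By default only the climate series is resampled; a flag resamples both.
The Mann–Kendall test and an OLS slope describe the observed correlation
trend, with a slope interval from the bootstrap slope distribution.

## Phenology

NDVI trajectories are fitted per pixel-year with a first-order harmonic of
period 365 days over Julian days 1–212 (January through July), by ordinary
least squares with cloud-masked observations simply omitted; at least 8
observations spanning at least 120 days are required. A single-peak
seasonal trajectory motivates order one. Curve extrema are evaluated in
closed form on the continuous window t ∈ [0, 212] (t = 0 is the start of
January 1), and the start of season is the first rising crossing of
NDVI₅₀ = min + 0.5·(max − min), solved in closed form and cross-checked
against root-finding in the tests. When no rising crossing exists in the
window (fitted minimum after the maximum), the pixel-year is flagged
ambiguous instead of being dated. Sensitivity is the OLS slope α of
start-of-season day on MAM temperature (days/°C, negative = earlier
green-up when warmer) with its Pearson r, over ≥ 5 shared years; maps are
summarised by forest cover class (upland conifer, lowland conifer, oak
savannah, upland deciduous), with unclassified pixels counted separately.

## Synthetic data

All generators are pure functions of a config (seed included) and draw
from named substreams of one root seed, so outputs are bit-reproducible.
AR(1) noise is parameterised by its marginal variance — the quantity a
data analyst can estimate — with innovation variance derived internally.

- Spring temperature: piecewise mean with a break after 1976 (pre 3.33 °C,
  variance 1.33; post 4.60 °C, variance 3.00 — the effect size of the
  station record the pipeline is designed around), optional linear trend
  (default 0), AR(1) noise with lag-1 autocorrelation 0.2 over 1911–2020.
- Circulation index: standardised monthly AR(1) (lag-1 0.5) with an
  optional sustained positive excursion (default +1σ over winters
  1977–1988, mimicking a prolonged positive circulation phase).
- Ring widths: negative-exponential age curve × exp(β(t)·z_climate +
  releases + tree noise + core noise), 15 trees × 2 cores sharing the
  tree-level signal, β ramping 0 → 0.6 by default; widths are lognormal by
  construction (positive) and rounded to the 0.001 mm measurement
  resolution of a stage micrometer.
- NDVI stacks: per pixel-year a harmonic whose rising 50% crossing sits at
  base_day + α·(T − T̄) + noise, α = −3 days/°C, observed every 8 days with
  20% of observations removed; a cover raster assigns the four classes
  round-robin, with optional per-class α.
- Monthly grid: cell value = seasonal climatology + loading(cell) × winter
  index + noise, with a west-to-east gradient loading by default, on
  0.5°-centre coordinates.

What the generators do **not** emulate: spatially correlated noise beyond
the loading pattern, precipitation/drought covariability, observation
inhomogeneities (station moves, sensor changes), cloud-mask seasonality in
NDVI, and disturbance processes beyond simple step releases. Passing tests
therefore demonstrate statistical correctness of the methods under the
stated noise structure, not robustness to every artefact of real records.

## Problem sizes used in the test suite

The statistical acceptance checks run at the sizes that make their targets
meaningful while keeping the suite quick: 200 replicates for regime
recovery and null calibration (series length 110), 2000 replicates for the
Mann–Kendall size check (n = 100), 10 independent 300-year pairs × 1000
bootstrap iterations for null coverage, and 200 pixels × 19 years for α
recovery. The end-to-end pipeline smoke runs with 8 trees, 48 pixels and a
4×4 grid.

## Known limitations

- The one-vs-two-state likelihood-ratio test ignores the boundary
  non-regularity (documented above); its empirical size is checked, not
  derived.
- At the default effect size (~0.9σ mean shift with AR(1) noise), the
  maximum-likelihood two-state fit frequently decodes to a path with more
  than one switch, and even a purpose-built two-segment changepoint
  estimator localises the break within ±3 years only ~60% of the time.
  Transition-year output should be read as "a single stable transition was
  found here", not as a guaranteed-accurate break date.
- The variance floor and EM rollback make fitting robust but mean the
  returned solution can be a boundary-constrained local optimum.
- Spearman p-values for 10-year overlaps fall back to exact enumeration,
  which is exact but slow per cell; maps at that overlap length should be
  small.
- The spline detrend's frequency response is exact for interior points of
  long series; near the ends the effective stiffness differs, as with any
  penalised smoother.
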