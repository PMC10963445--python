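# springshift

Regime-shift detection and forest climate-sensitivity analysis for spring
temperature records.

## The problem

Across the western Great Lakes region, the transition from winter to spring
has warmed faster than any other season, and the warming is not a smooth
ramp: North Pacific circulation (the Pacific–North America pattern, PNA)
shifted phase in the winter of 1976/77, producing an abrupt, persistent
change in the mean state of spring (March–April–May) temperature on top of
the secular greenhouse-gas trend. `springshift` is a toolkit for analysts
who want to (1) detect such regime changes in annual climate and
tree-growth series, (2) attribute regional warming by comparing station and
gridded records with forced climate-model ensembles and unforced control
runs, (3) map winter-circulation teleconnections, and (4) quantify how
forest growth (tree-ring widths) and canopy phenology (satellite NDVI
green-up) respond to spring temperature.

Everything runs on plain annual series, Tucson RWL ring-width files, CSV
station/index tables, and CF-style NetCDF monthly grids. A seeded
synthetic-data module generates inputs with the statistical structure every
stage assumes, so the full pipeline is testable offline.

## The models

**Regime detection.** A K-state Gaussian hidden Markov model: observations
X_t are emitted from hidden climate states S_t ∈ {1..K} with

    p(X_t | S_t = k) = N(X_t | μ_k, σ_k²),

and S_t evolves with transition matrix Γ. Transitions may depend on
covariates z_t (a forced-warming curve, a winter circulation index) through
a row-wise multinomial logit, P(S_{t+1}=j | S_t=i, z_t) ∝ exp(a_ij + b_ij·z_t).
Fitting is by EM (forward–backward in log terms); one-state, two-state and
covariate models are compared by AIC, BIC and likelihood-ratio tests, and a
two-state fit is summarised by its transition year — the last year in the
first state, reported only when the decoded path switches exactly once.

**Attribution.** OLS decadal trends and total warming over a common window
(e.g. 1961–2010 = 4.9 decades), Mann–Kendall trend significance, pre/post
break mean and variance comparison with a two-sided F test, and resampling
of a long pre-industrial control run into 100 × 50-year segments to
characterise unforced variability.

**Teleconnections.** Cell-wise Spearman rank correlation of DJFM winter
index means (labelled by the January year) against MAM gridded temperature,
with a two-sided significance mask.

**Dendro.** Negative-exponential or smoothing-spline detrending (50%
frequency response at a 100-year wavelength), chronology averaging with
RBAR and EPS = n·rbar/(n·rbar + 1 − rbar), 10-year running Pearson
correlations against climate, and a block-bootstrap null (10-year blocks,
1000 iterations) for the Mann–Kendall trend in those correlations.

**Phenology.** Per pixel-year, a first-order harmonic is least-squares fit
to NDVI on Julian days 1–212; the start of season is the day the fitted
curve first crosses NDVI₅₀ = NDVI_min + 0.5 (NDVI_max − NDVI_min) while
rising. Green-up dates are regressed on MAM temperature per pixel (slope α
in days/°C), and sensitivities are summarised by forest cover class.

## Worked example

```python
import numpy as np
import springshift as ss
from springshift.synthetic_data import (
    GeneratorConfig, gen_spring_temperature, gen_circulation_index)
from springshift.io_formats import winter_mean_index
from springshift.attribution import decadal_trend, pre_post_comparison

cfg = GeneratorConfig(seed=42)          # 1911-2020, shift after 1976
temp = gen_spring_temperature(cfg)
widx = winter_mean_index(gen_circulation_index(cfg)).dropna()
common = np.intersect1d(temp.years, widx.years)
cov = widx.values[np.isin(widx.years, common)]

suite = ss.fit_model_suite(temp, covariates=cov, covariate_years=common, seed=0)
print(suite.round(2).to_string(index=False))

tr = decadal_trend(temp, (1961, 2010))
pp = pre_post_comparison(temp, 1976)
print("trend %.3f C/decade, total %.2f C" % (tr.slope, tr.total_change))
print("pre %.2f (var %.2f)  post %.2f (var %.2f)" %
      (pp.pre_mean, pp.pre_var, pp.post_mean, pp.post_var))
```

prints

```
           model  n_states  n_covariates    aic    bic  loglik  delta_aic  lrt_p significance      compared_to transition_year
       one_state         1             0 390.28 395.69 -193.14        NaN    NaN                                          <NA>
       two_state         2             0 385.13 404.03 -185.57      -5.15   0.01           **        one_state            1975
two_state_window         2             0 382.93 401.77 -184.47        NaN    NaN                                          1975
   two_state_cov         2             1 383.27 407.50 -182.64       0.34   0.16         none two_state_window            <NA>
trend 0.250 C/decade, total 1.23 C
pre 3.34 (var 1.20)  post 4.17 (var 2.79)
```

The two-state model beats the one-state null by ΔAIC = −5.15 with a
significant likelihood ratio, and the decoded path switches once, placing
the regime transition at 1975 — one year off the generating 1976/77 break
for this particular noise draw. On the shorter covariate window the
circulation covariate raises the log-likelihood but not enough to justify
its extra parameters. The trend/total-warming and pre/post rows recover the
generating step (pre mean 3.33, post mean 4.60 °C in expectation; a single
draw scatters around those values).

The same analyses are available from the command line:

```sh
springshift simulate --preset all --seed 1 --out sim/
springshift regimes --input sim/spring_temperature.csv --report regimes.csv
springshift run-all --seed 1 --out results/
```

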