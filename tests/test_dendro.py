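"""Detrending, chronology statistics, and block-bootstrap running correlations."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from springshift.dendro import (
    block_bootstrap_significance,
    build_chronology,
    detrend_negexp,
    detrend_spline,
    running_correlation,
    DetrendResult,
)
from springshift.io_formats import AnnualSeries, RingSeries


class TestNegExp:
    def test_noiseless_curve_recovered(self):
        t = np.arange(120, dtype=float)
        w = 2.0 * np.exp(-0.05 * t) + 0.3
        res = detrend_negexp(RingSeries("X", 1900, w))
        assert res.method == "negexp"
        np.testing.assert_allclose(res.fitted, w, atol=1e-6)
        np.testing.assert_allclose(res.index, 1.0, atol=1e-6)

    def test_constant_series_falls_back_to_mean(self):
        res = detrend_negexp(RingSeries("X", 1900, np.full(50, 1.7)))
        assert res.fallback
        np.testing.assert_allclose(res.index, 1.0)

    def test_increasing_series_takes_fallback(self):
        w = 0.5 + 0.02 * np.arange(60)
        res = detrend_negexp(RingSeries("X", 1900, w))
        assert res.fallback
        assert res.method == "mean"

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            detrend_negexp(RingSeries("X", 1900, np.zeros(30)))

    def test_index_mean_near_one_on_noisy_input(self, rng):
        t = np.arange(150, dtype=float)
        w = (1.5 * np.exp(-0.03 * t) + 0.5) * np.exp(rng.normal(0, 0.1, t.size))
        res = detrend_negexp(RingSeries("X", 1850, w))
        assert abs(res.index.mean() - 1.0) < 0.02


class TestSpline:
    def test_linear_series_reproduced_exactly(self):
        w = 2.0 + 0.01 * np.arange(200)
        res = detrend_spline(RingSeries("X", 1800, w))
        np.testing.assert_allclose(res.index, 1.0, atol=1e-6)

    def test_century_sinusoid_attenuated_to_half(self):
        t = np.arange(300, dtype=float)
        w = 2.0 + 0.3 * np.sin(2 * np.pi * t / 100.0)
        res = detrend_spline(RingSeries("X", 1700, w), wavelength=100.0)
        amp = _fitted_amplitude(res, period=100.0)
        assert amp / 0.3 == pytest.approx(0.5, abs=0.05)

    def test_decadal_sinusoid_passes_through(self):
        t = np.arange(300, dtype=float)
        w = 2.0 + 0.3 * np.sin(2 * np.pi * t / 10.0)
        res = detrend_spline(RingSeries("X", 1700, w), wavelength=100.0)
        amp = _fitted_amplitude(res, period=10.0)
        assert amp / 0.3 < 0.05

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detrend_spline(RingSeries("X", 2000, np.ones(15)))


def _fitted_amplitude(res: DetrendResult, period: float) -> float:
    t = np.arange(res.fitted.size, dtype=float)
    interior = slice(50, res.fitted.size - 50)
    X = np.column_stack([np.sin(2 * np.pi * t / period),
                         np.cos(2 * np.pi * t / period)])
    y = res.fitted - res.fitted[interior].mean()
    coef, *_ = np.linalg.lstsq(X[interior], y[interior], rcond=None)
    return float(np.hypot(*coef))


class TestChronology:
    @staticmethod
    def _as_detrended(sid, first_year, index):
        idx = np.asarray(index, float)
        years = first_year + np.arange(idx.size)
        return DetrendResult(sid, years, idx, np.ones_like(idx), "negexp")

    def test_identical_series_perfect_agreement(self, rng):
        vals = 1.0 + 0.1 * rng.normal(size=40)
        detr = [self._as_detrended(f"S{i}", 1950, vals) for i in range(3)]
        ch = build_chronology(detr)
        assert ch.rbar == pytest.approx(1.0)
        assert ch.eps == pytest.approx(1.0)
        np.testing.assert_allclose(ch.index, vals)

    def test_three_series_hand_computed_rbar_eps(self):
        a = np.array([1.0, 1.2, 0.9, 1.1, 0.8, 1.3, 1.0, 0.7])
        b = np.array([1.1, 1.0, 0.8, 1.2, 0.9, 1.2, 1.1, 0.8])
        c = np.array([0.9, 1.1, 1.0, 1.0, 0.7, 1.4, 0.9, 0.9])
        detr = [self._as_detrended(s, 1990, v) for s, v in zip("ABC", (a, b, c))]
        ch = build_chronology(detr)
        r_ab = pearsonr(a, b).statistic
        r_ac = pearsonr(a, c).statistic
        r_bc = pearsonr(b, c).statistic
        rbar = (r_ab + r_ac + r_bc) / 3.0
        eps = 3.0 * rbar / (3.0 * rbar + 1.0 - rbar)
        assert ch.rbar == pytest.approx(rbar, abs=1e-12)
        assert ch.eps == pytest.approx(eps, abs=1e-12)
        np.testing.assert_allclose(ch.index, (a + b + c) / 3.0)
        np.testing.assert_array_equal(ch.sample_depth, 3)

    def test_eps_cutoff_flag(self):
        strong = [self._as_detrended(s, 2000, v) for s, v in
                  zip("AB", (np.arange(10.0), np.arange(10.0) + 0.01))]
        assert build_chronology(strong).passes_eps_cutoff

    def test_eps_monotone_in_rbar_and_depth(self):
        def eps(n, r):
            return n * r / (n * r + 1 - r)
        rs = np.linspace(0.05, 0.95, 10)
        assert np.all(np.diff([eps(10, r) for r in rs]) > 0)
        ns = np.arange(2, 30)
        assert np.all(np.diff([eps(n, 0.3) for n in ns]) > 0)

    def test_single_series_rejected(self):
        with pytest.raises(ValueError):
            build_chronology([self._as_detrended("A", 2000, np.ones(5))])

    def test_disjoint_series_rejected(self):
        detr = [self._as_detrended("A", 1900, np.arange(10.0) + 1),
                self._as_detrended("B", 2000, np.arange(10.0) + 1)]
        with pytest.raises(ValueError):
            build_chronology(detr)


class TestRunningCorrelation:
    def test_identical_series_all_ones(self, rng):
        years = np.arange(1950, 2000)
        vals = rng.normal(size=50)
        a = AnnualSeries("a", years, vals)
        rc = running_correlation(a, AnnualSeries("b", years, vals.copy()))
        np.testing.assert_allclose(rc.r, 1.0, atol=1e-10)

    def test_anticorrelated_pair_minus_one(self, rng):
        years = np.arange(1950, 2000)
        vals = rng.normal(size=50)
        rc = running_correlation(AnnualSeries("a", years, vals),
                                 AnnualSeries("b", years, -vals))
        np.testing.assert_allclose(rc.r, -1.0, atol=1e-10)

    def test_single_window_hand_computed(self):
        years = np.arange(2000, 2010)
        a = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0, 5.5, 7.0, 6.5, 8.0])
        b = np.array([2.0, 2.5, 2.2, 4.0, 3.5, 5.0, 5.2, 6.1, 6.0, 7.2])
        rc = running_correlation(AnnualSeries("a", years, a),
                                 AnnualSeries("b", years, b), window=10)
        assert rc.r[0] == pytest.approx(pearsonr(a, b).statistic, abs=1e-12)
        assert rc.window_centers[0] == pytest.approx(2004.5)

    def test_short_overlap_rejected(self, rng):
        years = np.arange(2000, 2006)
        a = AnnualSeries("a", years, rng.normal(size=6))
        b = AnnualSeries("b", years, rng.normal(size=6))
        with pytest.raises(ValueError):
            running_correlation(a, b, window=10)


class TestBlockBootstrap:
    def test_seeded_rerun_identical(self, rng):
        years = np.arange(1900, 2000)
        a = AnnualSeries("a", years, rng.normal(size=100))
        b = AnnualSeries("b", years, rng.normal(size=100))
        r1 = block_bootstrap_significance(a, b, n_iter=200, seed=3)
        r2 = block_bootstrap_significance(a, b, n_iter=200, seed=3)
        assert r1.null_threshold == r2.null_threshold
        assert r1.slope_ci == r2.slope_ci

    def test_block_longer_than_series_rejected(self, rng):
        years = np.arange(2000, 2015)
        a = AnnualSeries("a", years, rng.normal(size=15))
        b = AnnualSeries("b", years, rng.normal(size=15))
        with pytest.raises(ValueError):
            block_bootstrap_significance(a, b, block=30, n_iter=100)

    def test_few_iterations_warn(self, rng):
        years = np.arange(1950, 2010)
        a = AnnualSeries("a", years, rng.normal(size=60))
        b = AnnualSeries("b", years, rng.normal(size=60))
        with pytest.warns(UserWarning):
            block_bootstrap_significance(a, b, n_iter=50, seed=0)

    def test_strengthening_coupling_detected(self, rng):
        # growth coupling to climate ramps 0 -> 0.8: the running correlation
        # should trend upward with a significant Mann-Kendall result
        detections = 0
        n_rep = 12
        for rep in range(n_rep):
            years = np.arange(1900, 2020)
            clim = rng.normal(size=years.size)
            beta = np.linspace(0.0, 0.8, years.size)
            growth = beta * clim + rng.normal(0, np.sqrt(1 - beta ** 2))
            rc = block_bootstrap_significance(
                AnnualSeries("g", years, growth),
                AnnualSeries("c", years, clim), n_iter=200, seed=rep)
            if rc.mk_p < 0.05 and rc.slope > 0:
                detections += 1
        assert detections >= 0.9 * n_rep
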