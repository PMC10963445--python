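"""Gaussian hidden Markov models with covariate-dependent transitions.

A K-state model emits annual observations from state-specific Gaussian
distributions N(mu_k, sigma_k^2).  The hidden state evolves as a Markov
chain whose transition matrix may depend on external covariates (here,
typically a forced-warming curve and a winter circulation index) through a
row-wise multinomial-logit link with each row's own state as the reference
category:

    P(S_{t+1} = j | S_t = i, z_t)  propto  exp(a_ij + b_ij . z_t),   a_ii = 0

With no covariates the model reduces exactly to a homogeneous Gaussian HMM.
Fitting is by EM (forward-backward in log space; closed-form emission
updates; weighted multinomial-logit maximisation for the transition
parameters when covariates are present), with seeded random restarts.
Models are compared by AIC/BIC and likelihood-ratio tests, and a fitted
two-state model is summarised by its transition year: the last year spent
in the initial state, reported only when the decoded path switches state
exactly once.

States are canonicalised so state 0 carries the lower emission mean, making
"cool regime -> warm regime" transition years deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp, softmax
from scipy.stats import chi2

from .io_formats import AnnualSeries

__all__ = [
    "HMMParams",
    "HMMFitResult",
    "ModelComparison",
    "count_free_params",
    "log_forward",
    "posterior_decode",
    "fit_em",
    "identify_transition_year",
    "information_criteria",
    "compare_models",
    "fit_model_suite",
]

_SD_FLOOR_FRAC = 1e-3  # variance floor, as a fraction of the pooled sd


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class HMMParams:
    """Parameters of a K-state Gaussian HMM.

    ``trans_base`` is the row-stochastic transition matrix at covariate
    value zero; ``trans_coefs`` (K, K, p) holds the logit coefficients on p
    covariates for the off-diagonal categories (diagonal entries are the
    reference and fixed at zero).
    """

    init_probs: np.ndarray
    trans_base: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    trans_coefs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.init_probs = np.asarray(self.init_probs, float)
        self.trans_base = np.asarray(self.trans_base, float)
        self.means = np.asarray(self.means, float)
        self.sds = np.asarray(self.sds, float)
        K = self.n_states
        if self.trans_base.shape != (K, K):
            raise ValueError("trans_base must be K x K")
        if not np.allclose(self.trans_base.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("trans_base rows must sum to 1")
        if not np.isclose(self.init_probs.sum(), 1.0, atol=1e-8):
            raise ValueError("init_probs must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("emission sds must be positive")
        if self.trans_coefs is not None:
            self.trans_coefs = np.asarray(self.trans_coefs, float)
            if self.trans_coefs.shape[:2] != (K, K):
                raise ValueError("trans_coefs must be K x K x p")

    @property
    def n_states(self) -> int:
        return int(self.means.size)

    @property
    def n_covariates(self) -> int:
        return 0 if self.trans_coefs is None else self.trans_coefs.shape[2]

    def transition_logits(self) -> np.ndarray:
        """Row-wise logit intercepts a_ij = log(P_ij / P_ii), a_ii = 0."""
        P = np.clip(self.trans_base, 1e-300, None)
        return np.log(P) - np.log(np.diag(P))[:, None]

    def transition_matrices(self, Z: np.ndarray | None, T: int) -> np.ndarray:
        """Transition matrix for each step t -> t+1; shape (T-1, K, K).

        ``Z`` holds the covariate row governing each transition (aligned to
        the origin step t), or None for a homogeneous chain.
        """
        K = self.n_states
        A = self.transition_logits()
        if self.n_covariates == 0 or Z is None:
            P = softmax(A, axis=1)
            return np.broadcast_to(P, (max(T - 1, 0), K, K))
        Z = np.asarray(Z, float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] < T - 1:
            raise ValueError("covariate rows must cover every transition step")
        eta = A[None, :, :] + np.einsum("ijp,tp->tij", self.trans_coefs, Z[: T - 1])
        return softmax(eta, axis=2)


@dataclass
class HMMFitResult:
    """A fitted model with its diagnostics."""

    params: HMMParams
    loglik: float
    n_free_params: int
    aic: float
    bic: float
    posteriors: np.ndarray
    map_path: np.ndarray
    converged: bool
    n_iter: int
    seed: int
    years: np.ndarray | None = None
    transition_year: int | None = None
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_obs(self) -> int:
        return self.posteriors.shape[0]


@dataclass
class ModelComparison:
    delta_aic: float
    delta_bic: float
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    significance_code: str


def count_free_params(K: int, p: int = 0) -> int:
    """Free parameters: (K-1) initial + K(K-1)(1+p) transition + 2K emission."""
    return (K - 1) + K * (K - 1) * (1 + p) + 2 * K


def information_criteria(loglik: float, n_free_params: int, T: int) -> tuple[float, float]:
    """AIC = 2k - 2 logL; BIC = k ln T - 2 logL."""
    if T < 1:
        raise ValueError("T must be >= 1")
    aic = 2.0 * n_free_params - 2.0 * loglik
    bic = n_free_params * np.log(T) - 2.0 * loglik
    return aic, bic


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


def _as_obs(obs) -> np.ndarray:
    x = obs.values if isinstance(obs, AnnualSeries) else np.asarray(obs, float)
    x = np.asarray(x, float)
    if x.ndim != 1:
        raise ValueError("observations must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("observations contain missing/non-finite values; "
                         "split the series at gaps before fitting")
    return x


def _log_emissions(x: np.ndarray, params: HMMParams) -> np.ndarray:
    z = (x[:, None] - params.means[None, :]) / params.sds[None, :]
    return -0.5 * z * z - np.log(params.sds)[None, :] - 0.5 * np.log(2.0 * np.pi)


def _check_covariates(Z, T: int, p: int) -> np.ndarray | None:
    if p == 0:
        return None
    if Z is None:
        raise ValueError("model has covariates but none were supplied")
    Z = np.asarray(Z, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] not in (T, T - 1) or Z.shape[1] != p:
        raise ValueError(f"covariates must be ({T} or {T - 1}) x {p}")
    return Z


def log_forward(obs, params: HMMParams, covariates=None) -> float:
    """Log-likelihood log p(x_1..T) via the forward algorithm in log space."""
    x = _as_obs(obs)
    T, K = x.size, params.n_states
    if K < 1:
        raise ValueError("model must have at least one state")
    Z = _check_covariates(covariates, T, params.n_covariates)
    logB = _log_emissions(x, params)
    logP = np.log(np.clip(params.transition_matrices(Z, T), 1e-300, None))
    alpha = np.log(np.clip(params.init_probs, 1e-300, None)) + logB[0]
    for t in range(1, T):
        alpha = logsumexp(alpha[:, None] + logP[t - 1], axis=0) + logB[t]
    return float(logsumexp(alpha))


def _forward_backward(x: np.ndarray, params: HMMParams, Z: np.ndarray | None):
    """Scaled forward-backward; returns (loglik, gamma, xi).

    Emission densities are normalised per step before entering the scaled
    recursion, so the computation is exact in log terms while running in
    fast linear arithmetic.
    """
    T, K = x.size, params.n_states
    logB = _log_emissions(x, params)
    bmax = logB.max(axis=1)
    B = np.exp(logB - bmax[:, None])
    P = params.transition_matrices(Z, T)
    alpha = np.empty((T, K))
    scale = np.empty(T)
    a = params.init_probs * B[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ P[t - 1]) * B[t]
        s = a.sum()
        scale[t] = s
        alpha[t] = a / s
    loglik = float(np.log(scale).sum() + bmax.sum())
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (P[t] @ (B[t + 1] * beta[t + 1])) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    if T > 1:
        xi = (alpha[:-1, :, None] * P
              * (B[1:] * beta[1:])[:, None, :] / scale[1:, None, None])
        xi /= xi.sum(axis=(1, 2), keepdims=True)
    else:
        xi = np.zeros((0, K, K))
    return loglik, gamma, xi


def _viterbi(x: np.ndarray, params: HMMParams, Z: np.ndarray | None) -> np.ndarray:
    T, K = x.size, params.n_states
    logB = _log_emissions(x, params)
    logP = np.log(np.clip(params.transition_matrices(Z, T), 1e-300, None))
    delta = np.log(np.clip(params.init_probs, 1e-300, None)) + logB[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logP[t - 1]
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def posterior_decode(obs, params: HMMParams, covariates=None):
    """Posterior state probabilities (forward-backward) and the Viterbi path."""
    x = _as_obs(obs)
    Z = _check_covariates(covariates, x.size, params.n_covariates)
    _, gamma, _ = _forward_backward(x, params, Z)
    return gamma, _viterbi(x, params, Z)


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------


def _init_params(x: np.ndarray, K: int, p: int, rng: np.random.Generator,
                 jitter: bool) -> HMMParams:
    # Conservative prior on regime persistence: start almost surely in the
    # first state, with sticky (0.9 diagonal) transitions.
    pi = np.full(K, 0.05 / max(K - 1, 1))
    pi[0] = 0.95
    if K == 1:
        pi = np.array([1.0])
    A = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(A, 0.9)
    A /= A.sum(axis=1, keepdims=True)
    qs = np.linspace(25, 75, K) if K > 1 else np.array([50.0])
    means = np.percentile(x, qs)
    sd = float(np.std(x))
    sd = sd if sd > 0 else 1.0
    if jitter:
        means = means + rng.uniform(-0.5, 0.5, K) * sd
    sds = np.full(K, sd)
    coefs = np.zeros((K, K, p)) if p > 0 else None
    return HMMParams(pi, A, means, sds, coefs)


def _mstep_transitions(params: HMMParams, xi: np.ndarray,
                       Z: np.ndarray | None) -> tuple[np.ndarray, np.ndarray | None]:
    """Maximise the expected transition log-likelihood.

    With no covariates the update is the classical count ratio.  With
    covariates each row i is a weighted multinomial logit (reference =
    staying in state i) maximised with BFGS, warm-started at the current
    parameters.
    """
    K = params.n_states
    p = params.n_covariates
    if p == 0 or Z is None:
        counts = xi.sum(axis=0)
        rows = counts.sum(axis=1, keepdims=True)
        A = np.where(rows > 0, counts / np.where(rows > 0, rows, 1.0), 1.0 / K)
        A = np.clip(A, 1e-12, None)
        A /= A.sum(axis=1, keepdims=True)
        return A, None

    Zt = Z[: xi.shape[0]]
    a0 = params.transition_logits()
    b0 = params.trans_coefs
    new_a = np.zeros((K, K))
    new_b = np.zeros((K, K, p))
    others = [[j for j in range(K) if j != i] for i in range(K)]

    for i in range(K):
        idx = others[i]
        w = xi[:, i, :]  # (T-1, K) expected transitions out of state i

        def negq(theta, i=i, idx=idx, w=w):
            a = theta[: K - 1]
            b = theta[K - 1:].reshape(K - 1, p)
            eta = np.zeros((Zt.shape[0], K))
            eta[:, idx] = a[None, :] + Zt @ b.T
            lse = logsumexp(eta, axis=1)
            val = -(np.sum(w * eta) - np.sum(w.sum(axis=1) * lse))
            # gradient
            prob = np.exp(eta - lse[:, None])
            resid = w - w.sum(axis=1, keepdims=True) * prob
            ga = -resid[:, idx].sum(axis=0)
            gb = -(resid[:, idx].T @ Zt)
            return val, np.concatenate([ga, gb.ravel()])

        theta0 = np.concatenate([a0[i, idx], b0[i, idx, :].ravel()])
        res = optimize.minimize(negq, theta0, jac=True, method="BFGS",
                                options={"maxiter": 200, "gtol": 1e-7})
        theta = res.x if res.fun <= negq(theta0)[0] + 1e-12 else theta0
        new_a[i, idx] = theta[: K - 1]
        new_b[i, idx, :] = theta[K - 1:].reshape(K - 1, p)

    base = softmax(new_a, axis=1)
    return base, new_b


def fit_em(obs, K: int, covariates=None, n_restarts: int = 3, tol: float = 1e-6,
           max_iter: int = 300, seed: int = 0) -> HMMFitResult:
    """Fit a K-state Gaussian HMM by EM with seeded random restarts.

    ``obs`` may be an :class:`AnnualSeries` (years are then attached to the
    result and a transition year extracted) or a plain array.  Covariates
    are standardised over the fitting window before entering the logit.
    """
    years = obs.years if isinstance(obs, AnnualSeries) else None
    x = _as_obs(obs)
    T = x.size
    if K < 1:
        raise ValueError("K must be >= 1")
    if T < 2 * K:
        raise ValueError(f"need at least {2 * K} observations for K={K}")
    p = 0
    Z = None
    if covariates is not None:
        Z = np.asarray(covariates, float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != T:
            raise ValueError("covariate rows must align with observations")
        sd = Z.std(axis=0)
        Z = (Z - Z.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        p = Z.shape[1]

    pooled_sd = float(np.std(x)) or 1.0
    sd_floor = _SD_FLOOR_FRAC * pooled_sd
    rng = np.random.default_rng(seed)

    best: tuple[float, HMMParams, bool, int, np.ndarray] | None = None
    last_error: Exception | None = None
    for restart in range(max(1, n_restarts)):
        params = _init_params(x, K, p, rng, jitter=restart > 0)
        trace: list[float] = []
        prev_ll = -np.inf
        prev_params = params
        prev_gamma = None
        converged = False
        try:
            for it in range(max_iter):
                ll, gamma, xi = _forward_backward(x, params, Z)
                if ll < prev_ll - 1e-8:
                    # a constrained M-step (variance floor) can break strict
                    # ascent near a degenerate state: keep the last good
                    # iterate instead of discarding the restart
                    params, gamma = prev_params, prev_gamma
                    break
                trace.append(ll)
                if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol:
                    converged = True
                    break
                prev_ll = ll
                prev_params = params
                prev_gamma = gamma
                # M-step
                pi = np.clip(gamma[0], 1e-12, None)
                pi /= pi.sum()
                w = gamma.sum(axis=0)
                means = (gamma.T @ x) / w
                var = (gamma.T @ (x[:, None] - means[None, :]) ** 2
                       )[np.arange(K), np.arange(K)] / w
                sds = np.maximum(np.sqrt(var), sd_floor)
                base, coefs = _mstep_transitions(params, xi, Z) if T > 1 else (
                    params.trans_base, params.trans_coefs)
                params = HMMParams(pi, base, means, sds, coefs)
        except RuntimeError as exc:
            last_error = exc
            continue
        # a converged fit must give every state at least two observations
        # worth of posterior mass; thinner states are degenerate spikes
        if K > 1 and np.any(gamma.sum(axis=0) < 2.0 - 1e-9):
            last_error = RuntimeError("degenerate state (posterior mass < 2 obs)")
            continue
        final_ll = trace[-1]
        if best is None or final_ll > best[0]:
            best = (final_ll, params, converged, len(trace), np.asarray(trace))

    if best is None:
        raise RuntimeError(f"EM failed on all restarts: {last_error}")

    loglik, params, converged, n_iter, trace = best
    params = _canonicalize(params)
    gamma, path = posterior_decode(x, params, Z)
    k = count_free_params(K, p)
    aic, bic = information_criteria(loglik, k, T)
    tyear = identify_transition_year(path, years) if years is not None else None
    return HMMFitResult(params, loglik, k, aic, bic, gamma, path, converged,
                        n_iter, seed, years=years, transition_year=tyear,
                        loglik_trace=trace)


def _canonicalize(params: HMMParams) -> HMMParams:
    """Reorder states so emission means are ascending (state 0 = cool)."""
    order = np.argsort(params.means, kind="stable")
    if np.all(order == np.arange(params.n_states)):
        return params
    coefs = None
    if params.trans_coefs is not None:
        coefs = params.trans_coefs[np.ix_(order, order)]
    return HMMParams(params.init_probs[order],
                     params.trans_base[np.ix_(order, order)],
                     params.means[order], params.sds[order], coefs)


# ---------------------------------------------------------------------------
# Summaries and model comparison
# ---------------------------------------------------------------------------


def identify_transition_year(map_path: Sequence[int], years: Sequence[int]) -> int | None:
    """The single regime-change year, or None.

    If the decoded path switches state exactly once (1...1 2...2), the last
    year spent in the first state is returned; paths that revisit a state
    yield None.
    """
    path = np.asarray(map_path)
    years = np.asarray(years)
    if path.size != years.size:
        raise ValueError("path and years must align")
    if path.size < 2:
        return None
    switches = np.nonzero(np.diff(path) != 0)[0]
    if switches.size != 1:
        return None
    return int(years[switches[0]])


def _significance_code(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "·"
    return "none"


def compare_models(null_fit: HMMFitResult, alt_fit: HMMFitResult) -> ModelComparison:
    """Likelihood-ratio comparison of nested fits on the same observations."""
    if null_fit.n_obs != alt_fit.n_obs:
        raise ValueError("models were fitted on different observation windows")
    lrt = 2.0 * (alt_fit.loglik - null_fit.loglik)
    df = alt_fit.n_free_params - null_fit.n_free_params
    p = float(chi2.sf(lrt, df)) if df > 0 and lrt > 0 else 1.0
    return ModelComparison(alt_fit.aic - null_fit.aic, alt_fit.bic - null_fit.bic,
                           lrt, df, p, _significance_code(p))


def fit_model_suite(obs: AnnualSeries, covariates: pd.DataFrame | np.ndarray | None = None,
                    covariate_years: np.ndarray | None = None,
                    n_restarts: int = 3, seed: int = 0, tol: float = 1e-6,
                    max_iter: int = 300) -> pd.DataFrame:
    """Fit the one-state, two-state and two-state + covariate models.

    Returns a table with one row per model (AIC, BIC, logL, dAIC against the
    relevant simpler model, LRT p, transition year).  When covariates are
    supplied, the covariate model — and the two-state model it is compared
    against — are fitted on the window where all covariates exist, mirroring
    the shortening of the record that the covariates impose.
    """
    obs = obs.dropna()
    fits: dict[str, HMMFitResult] = {}
    rows: list[dict] = []

    fit1 = fit_em(obs, K=1, n_restarts=1, tol=tol, max_iter=max_iter, seed=seed)
    fit2 = fit_em(obs, K=2, n_restarts=n_restarts, tol=tol, max_iter=max_iter, seed=seed)
    fits["one_state"], fits["two_state"] = fit1, fit2
    cmp21 = compare_models(fit1, fit2)
    rows.append(_suite_row("one_state", fit1, None, None))
    rows.append(_suite_row("two_state", fit2, cmp21, "one_state"))

    if covariates is not None:
        Z = np.asarray(covariates, float)
        if Z.ndim == 1:
            Z = Z[:, None]
        zyears = np.asarray(covariate_years if covariate_years is not None else obs.years)
        valid = np.all(np.isfinite(Z), axis=1)
        common, io, iz = np.intersect1d(obs.years, zyears[valid], return_indices=True)
        if common.size < 4:
            raise ValueError("covariate/observation overlap is too short")
        sub = AnnualSeries(obs.site_id, common, obs.values[io], obs.season_label)
        Zsub = Z[valid][iz]
        fit2w = fit_em(sub, K=2, n_restarts=n_restarts, tol=tol,
                       max_iter=max_iter, seed=seed)
        fitc = fit_em(sub, K=2, covariates=Zsub, n_restarts=n_restarts, tol=tol,
                      max_iter=max_iter, seed=seed)
        fits["two_state_window"], fits["two_state_cov"] = fit2w, fitc
        rows.append(_suite_row("two_state_window", fit2w, None, None))
        rows.append(_suite_row("two_state_cov", fitc, compare_models(fit2w, fitc),
                               "two_state_window"))

    df = pd.DataFrame(rows)
    df.attrs["fits"] = fits
    return df


def _suite_row(name: str, fit: HMMFitResult, cmp: ModelComparison | None,
               against: str | None) -> dict:
    return {
        "model": name,
        "n_states": fit.params.n_states,
        "n_covariates": fit.params.n_covariates,
        "aic": fit.aic,
        "bic": fit.bic,
        "loglik": fit.loglik,
        "delta_aic": cmp.delta_aic if cmp else np.nan,
        "lrt_p": cmp.lrt_p if cmp else np.nan,
        "significance": cmp.significance_code if cmp else "",
        "compared_to": against or "",
        "transition_year": fit.transition_year if fit.transition_year is not None else pd.NA,
    }
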