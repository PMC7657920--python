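"""Gibbs sampler for the group factor analysis model.

Every latent block has a closed-form full conditional:

* ``Z`` — Gaussian, by conjugacy of the likelihood with the N(0, I) prior.
* ``(h_mk, w_:k^(m))`` — sampled as a block: the slab weights are
  integrated out analytically to give the Bernoulli conditional for the
  indicator, then weights are drawn from their Gaussian conditional when
  the indicator is on (exact zeros when off).  The blocked update
  avoids the mixing pathology of flipping ``h`` with ``w`` fixed.
* ``pi`` — Beta, by beta-Bernoulli conjugacy.
* ``alpha`` — Gamma where the indicator is on; refreshed from the prior
  where it is off, which keeps the chain invariant for the full joint.
* ``tau`` — Gamma, from the residual sums of squares over observed cells.

A sweep runs Z, then per view and component the blocked (h, w) update,
then pi, alpha, tau.  Missing cells are dropped from every sum in which
they would appear (ignorable missingness); no imputation is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .gfa_model import (
    GFAHyperparams,
    LatentState,
    ModelError,
    ViewData,
    log_joint,
)

__all__ = [
    "ChainConfig",
    "PosteriorSummary",
    "sample_Z_conditional",
    "sample_Wh_conditional",
    "wh_conditional_params",
    "sample_pi_conditional",
    "sample_alpha_conditional",
    "sample_tau_conditional",
    "gibbs_sweep",
    "run_chain",
]

_LOG_ODDS_CAP = 700.0   # keeps expit free of overflow warnings
_ALPHA_FLOOR = 1e-290   # underflow guard for vague Gamma draws


@dataclass
class ChainConfig:
    """Run protocol of a single Gibbs chain.

    Defaults follow the reference protocol: 2000 iterations with the
    first 90% as burn-in, leaving 200 retained draws.
    """

    n_iter: int = 2000
    burnin_frac: float = 0.9
    seed: int = 0
    thinning: int = 1

    def __post_init__(self) -> None:
        if self.n_iter < 1 or self.thinning < 1:
            raise ModelError("n_iter and thinning must be positive")
        if not 0 < self.burnin_frac < 1:
            raise ModelError("burnin_frac must lie in (0, 1)")
        if self.n_retained < 1:
            raise ModelError("configuration retains no posterior draws")

    @property
    def n_burnin(self) -> int:
        return int(round(self.n_iter * self.burnin_frac))

    @property
    def n_retained(self) -> int:
        return (self.n_iter - int(round(self.n_iter * self.burnin_frac))) // self.thinning


@dataclass
class PosteriorSummary:
    """Retained post-burn-in draws and streaming posterior moments.

    Small blocks (H, pi, Z) keep full draws; loadings and precisions —
    the large blocks at thousands of variables — keep streaming means
    and variances so memory stays bounded.
    """

    h_draws: np.ndarray           # S x M x K
    pi_draws: np.ndarray          # S x K
    z_draws: np.ndarray           # S x N x K
    w_mean: list[np.ndarray]      # per view, D_m x K
    w_var: list[np.ndarray]
    tau_mean: list[np.ndarray]
    alpha_mean: list[np.ndarray]
    log_joint_trace: np.ndarray   # n_iter
    view_names: list[str]
    var_names: list[Sequence[str] | None]
    pair_ids: Sequence[str] | None = None
    config: ChainConfig | None = None
    hyper: GFAHyperparams | None = None

    @property
    def n_retained(self) -> int:
        return self.h_draws.shape[0]

    @property
    def activity(self) -> np.ndarray:
        """Posterior inclusion probability per view x component (M x K)."""
        return self.h_draws.mean(axis=0)

    @property
    def z_mean(self) -> np.ndarray:
        return self.z_draws.mean(axis=0)

    @property
    def residual_variance(self) -> list[np.ndarray]:
        """Posterior-mean residual variance per variable (1 / E[tau])."""
        return [1.0 / t for t in self.tau_mean]


# ---------------------------------------------------------------------------
# full conditionals
# ---------------------------------------------------------------------------

def sample_Z_conditional(
    state: LatentState,
    views: Sequence[ViewData],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw Z from its Gaussian full conditional.

    For each sample ``n`` the precision is
    ``Lambda_n = I + sum_m W_o' diag(tau_o) W_o`` restricted to the
    observed cells of row ``n``, with mean ``Lambda_n^{-1} sum_m
    W_o' diag(tau_o) x_{n,o}``.
    """
    N, K = state.Z.shape
    rhs = np.zeros((N, K))
    lam_shared = np.eye(K)
    lam_per_n = None
    for m, view in enumerate(views):
        A = state.W[m] * state.tau[m][:, None]       # D x K
        rhs += view.filled() @ A
        if view.fully_observed:
            lam_shared += state.W[m].T @ A
        else:
            contrib = np.einsum(
                "nd,dk,dl->nkl", view.mask.astype(float), A, state.W[m], optimize=True
            )
            lam_per_n = contrib if lam_per_n is None else lam_per_n + contrib
    eps = rng.standard_normal((N, K))
    if lam_per_n is None:
        if not np.all(np.isfinite(lam_shared)):
            raise ModelError("non-finite precision matrix in Z update")
        L = np.linalg.cholesky(lam_shared)
        mu = np.linalg.solve(lam_shared, rhs.T).T
        # z = mu + L^{-T} eps has covariance Lambda^{-1}
        return mu + np.linalg.solve(L.T, eps.T).T
    lam = lam_shared[None, :, :] + lam_per_n
    if not np.all(np.isfinite(lam)):
        raise ModelError("non-finite precision matrix in Z update")
    L = np.linalg.cholesky(lam)                       # N x K x K
    mu = np.linalg.solve(lam, rhs[:, :, None])[:, :, 0]
    extra = np.linalg.solve(np.swapaxes(L, 1, 2), eps[:, :, None])[:, :, 0]
    return mu + extra


def _wh_params(
    r_masked: np.ndarray,
    zk: np.ndarray,
    zsq_obs: np.ndarray,
    tau: np.ndarray,
    alpha_k: np.ndarray,
    pi_k: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Parameters of the blocked (h, w) conditional for one view/component.

    ``r_masked`` is the residual excluding this component, with missing
    cells zeroed; ``zsq_obs[d] = sum over observed rows of z_nk^2``.
    The slab is integrated out: per variable, the marginal-likelihood
    ratio of slab vs spike is ``sqrt(alpha/lam) * exp(b^2 / (2 lam))``
    with ``lam = alpha + tau * zsq_obs`` and ``b = tau * sum z r``.
    Returns ``(p_on, mu, lam)``: the inclusion probability and the
    weight conditional N(mu, 1/lam) given inclusion.
    """
    s = tau * zsq_obs
    b = tau * (r_masked.T @ zk)
    lam = alpha_k + s
    if pi_k <= 0.0:
        p_on = 0.0
    elif pi_k >= 1.0:
        p_on = 1.0
    else:
        log_bf = 0.5 * (np.log(alpha_k) - np.log(lam)) + 0.5 * b * b / lam
        log_odds = math.log(pi_k) - math.log1p(-pi_k) + float(log_bf.sum())
        p_on = float(expit(min(max(log_odds, -_LOG_ODDS_CAP), _LOG_ODDS_CAP)))
    return p_on, b / lam, lam


def _wh_block(
    r_masked: np.ndarray,
    zk: np.ndarray,
    zsq_obs: np.ndarray,
    tau: np.ndarray,
    alpha_k: np.ndarray,
    pi_k: float,
    rng: np.random.Generator,
) -> tuple[int, np.ndarray]:
    """Blocked (h, w) draw from the parameters of :func:`_wh_params`."""
    p_on, mu, lam = _wh_params(r_masked, zk, zsq_obs, tau, alpha_k, pi_k)
    if p_on >= 1.0:
        h = 1
    elif p_on <= 0.0:
        h = 0
    else:
        h = int(rng.random() < p_on)
    if h:
        w = mu + rng.standard_normal(mu.shape) / np.sqrt(lam)
    else:
        w = np.zeros_like(mu)
    return h, w


def wh_conditional_params(
    state: LatentState,
    views: Sequence[ViewData],
    m: int,
    k: int,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Deterministic parameters of the blocked (h, w) conditional.

    Returns ``(p_on, mu, lam)``: the probability that component ``k``
    is active in view ``m`` given everything else, and the mean and
    precision of each weight's Gaussian conditional given inclusion.
    """
    view = views[m]
    resid_k = view.filled() - state.Z @ state.W[m].T + np.outer(
        state.Z[:, k], state.W[m][:, k]
    )
    maskf = view.mask.astype(float)
    zk = state.Z[:, k]
    return _wh_params(
        resid_k * maskf, zk, maskf.T @ (zk**2), state.tau[m],
        state.alpha[m][:, k], float(state.pi[k]),
    )


def sample_Wh_conditional(
    state: LatentState,
    views: Sequence[ViewData],
    m: int,
    k: int,
    rng: np.random.Generator,
) -> tuple[int, np.ndarray]:
    """Draw ``(h_mk, w_:k^(m))`` from the blocked conditional.

    Convenience form that rebuilds the residual from scratch; the chain
    runner maintains residuals incrementally but funnels through the
    same block update.
    """
    view = views[m]
    resid_k = view.filled() - state.Z @ state.W[m].T + np.outer(
        state.Z[:, k], state.W[m][:, k]
    )
    maskf = view.mask.astype(float)
    r_masked = resid_k * maskf
    zk = state.Z[:, k]
    zsq_obs = maskf.T @ (zk**2)
    return _wh_block(
        r_masked, zk, zsq_obs, state.tau[m], state.alpha[m][:, k],
        float(state.pi[k]), rng,
    )


def sample_pi_conditional(
    state: LatentState, hyper: GFAHyperparams, rng: np.random.Generator
) -> np.ndarray:
    """pi_k ~ Beta(a_pi + sum_m h_mk, b_pi + M - sum_m h_mk)."""
    s = state.H.sum(axis=0)
    M = state.n_views
    return rng.beta(hyper.a_pi + s, hyper.b_pi + M - s)


def sample_alpha_conditional(
    state: LatentState, hyper: GFAHyperparams, rng: np.random.Generator
) -> list[np.ndarray]:
    """ARD precisions: conjugate Gamma where on, prior refresh where off."""
    out = []
    for m in range(state.n_views):
        on = state.H[m].astype(bool)
        shape = np.where(on, hyper.a_alpha + 0.5, hyper.a_alpha)
        rate = np.where(on, hyper.b_alpha + 0.5 * state.W[m] ** 2, hyper.b_alpha)
        draws = rng.gamma(np.broadcast_to(shape, rate.shape), 1.0 / rate)
        # vague shapes (e.g. 1e-3) underflow to exact 0 with high probability
        out.append(np.maximum(draws, _ALPHA_FLOOR))
    return out


def sample_tau_conditional(
    state: LatentState,
    views: Sequence[ViewData],
    hyper: GFAHyperparams,
    rng: np.random.Generator,
    tau_rates: Sequence[np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Noise precisions from the conjugate Gamma over observed residuals."""
    out = []
    for m, view in enumerate(views):
        pred = state.Z @ state.W[m].T
        ssr = np.where(view.mask, (view.filled() - pred) ** 2, 0.0).sum(axis=0)
        n_obs = view.mask.sum(axis=0)
        b = (
            hyper.tau_rate(1.0) * np.ones(view.n_vars)
            if tau_rates is None
            else np.asarray(tau_rates[m], dtype=float)
        )
        out.append(rng.gamma(hyper.a_tau + 0.5 * n_obs, 1.0 / (b + 0.5 * ssr)))
    return out


# ---------------------------------------------------------------------------
# sweep and chain runner
# ---------------------------------------------------------------------------

def gibbs_sweep(
    state: LatentState,
    views: Sequence[ViewData],
    hyper: GFAHyperparams,
    rng: np.random.Generator,
    tau_rates: Sequence[np.ndarray] | None = None,
) -> LatentState:
    """One full sweep, updating the state in place and returning it.

    Order: Z, then per view/component the blocked (h, w), then pi,
    alpha, tau.  The per-view residual is maintained incrementally so a
    sweep costs O(N * sum_m D_m * K) regardless of K.
    """
    state.Z = sample_Z_conditional(state, views, rng)
    K = state.n_components
    for m, view in enumerate(views):
        E = view.filled() - state.Z @ state.W[m].T    # residual, garbage at missing
        maskf = None if view.fully_observed else view.mask.astype(float)
        if maskf is None:
            zsq = np.sum(state.Z**2, axis=0)          # per component, all rows
        else:
            zsq_mat = maskf.T @ (state.Z**2)          # D x K
        for k in range(K):
            zk = state.Z[:, k]
            w_old = state.W[m][:, k]
            Rk = E + np.outer(zk, w_old)
            if maskf is None:
                r_masked = Rk
                zsq_obs = np.full(view.n_vars, zsq[k])
            else:
                r_masked = Rk * maskf
                zsq_obs = zsq_mat[:, k]
            h, w = _wh_block(
                r_masked, zk, zsq_obs, state.tau[m], state.alpha[m][:, k],
                float(state.pi[k]), rng,
            )
            state.H[m, k] = h
            state.W[m][:, k] = w
            E = Rk - np.outer(zk, w)
    state.pi = sample_pi_conditional(state, hyper, rng)
    state.alpha = sample_alpha_conditional(state, hyper, rng)
    state.tau = sample_tau_conditional(state, views, hyper, rng, tau_rates)
    return state


def _initial_state(
    hyper: GFAHyperparams,
    views: Sequence[ViewData],
    rng: np.random.Generator,
    tau_rates: Sequence[np.ndarray],
) -> LatentState:
    """Dispersed but numerically tame starting point.

    All indicators start on with small random loadings; alpha and tau
    start at their prior means.  Starting from an exact prior draw is
    avoided because vague ARD priors can produce astronomically large
    initial loadings.
    """
    N = views[0].n_samples
    K = hyper.K
    M = len(views)
    W = [0.01 * rng.standard_normal((v.n_vars, K)) for v in views]
    alpha = [np.full((v.n_vars, K), hyper.a_alpha / hyper.b_alpha) for v in views]
    tau = [hyper.a_tau / np.asarray(tau_rates[m]) for m in range(M)]
    return LatentState(
        Z=rng.standard_normal((N, K)),
        W=W,
        H=np.ones((M, K), dtype=np.int8),
        pi=np.full(K, 0.5),
        alpha=alpha,
        tau=tau,
    )


def run_chain(
    views: Sequence[ViewData],
    hyper: GFAHyperparams,
    chain: ChainConfig | None = None,
    scale_free_views: Sequence[str] = ("genotype",),
    log_joint_every: int = 1,
) -> PosteriorSummary:
    """Run one Gibbs chain and summarize the retained draws.

    The informative noise prior is anchored at unit column variance for
    standardized views; views named in ``scale_free_views`` (the
    genotype view, which enters unscaled) anchor it at the observed
    column variance instead.

    Fully reproducible from ``chain.seed``: the same seed yields a
    bit-identical summary.
    """
    chain = chain or ChainConfig()
    if not views:
        raise ModelError("no views provided")
    N = views[0].n_samples
    for v in views:
        if v.n_samples != N:
            raise ModelError("views must share the same samples")
        if np.isnan(v.X[v.mask]).any():  # pragma: no cover - ViewData enforces this
            raise ModelError(f"view {v.name!r}: NaN outside missing mask")

    tau_rates = []
    for v in views:
        if v.name in scale_free_views:
            cv = v.observed_col_var()
            cv = np.where(np.isfinite(cv) & (cv > 0), cv, 1.0)
        else:
            cv = np.ones(v.n_vars)
        tau_rates.append(hyper.tau_rate(cv))

    rng = np.random.default_rng(chain.seed)
    state = _initial_state(hyper, views, rng, tau_rates)

    M, K = len(views), hyper.K
    S = chain.n_retained
    h_draws = np.empty((S, M, K), dtype=np.int8)
    pi_draws = np.empty((S, K))
    z_draws = np.empty((S, N, K))
    w_sum = [np.zeros((v.n_vars, K)) for v in views]
    w_sumsq = [np.zeros((v.n_vars, K)) for v in views]
    tau_sum = [np.zeros(v.n_vars) for v in views]
    alpha_sum = [np.zeros((v.n_vars, K)) for v in views]
    lj = np.full(chain.n_iter, np.nan)

    col_vars = [r / hyper.tau_rate(1.0) for r in tau_rates]
    s = 0
    for it in range(chain.n_iter):
        gibbs_sweep(state, views, hyper, rng, tau_rates)
        if log_joint_every and (it % log_joint_every == 0 or it == chain.n_iter - 1):
            lj[it] = log_joint(state, views, hyper, col_vars=col_vars).total
        post_burn = it - chain.n_burnin
        if post_burn >= 0 and post_burn % chain.thinning == 0 and s < S:
            h_draws[s] = state.H
            pi_draws[s] = state.pi
            z_draws[s] = state.Z
            for m in range(M):
                w_sum[m] += state.W[m]
                w_sumsq[m] += state.W[m] ** 2
                tau_sum[m] += state.tau[m]
                alpha_sum[m] += state.alpha[m]
            s += 1

    w_mean = [ws / s for ws in w_sum]
    w_var = [np.maximum(wsq / s - wm**2, 0.0) for wsq, wm in zip(w_sumsq, w_mean)]
    return PosteriorSummary(
        h_draws=h_draws[:s],
        pi_draws=pi_draws[:s],
        z_draws=z_draws[:s],
        w_mean=w_mean,
        w_var=w_var,
        tau_mean=[ts / s for ts in tau_sum],
        alpha_mean=[a / s for a in alpha_sum],
        log_joint_trace=lj,
        view_names=[v.name for v in views],
        var_names=[v.var_names for v in views],
        config=chain,
        hyper=hyper,
    )
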