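"""Generative model for multi-view group factor analysis (GFA).

The model couples ``M`` data views (matrices sharing N samples) through a
common latent space.  For sample ``n`` and view ``m``::

    x_n^(m) ~ N(W^(m) z_n, Sigma^(m)),      Sigma^(m) = diag(1 / tau^(m))
    z_n     ~ N(0, I_K)
    w_dk^(m) ~ h_mk * N(0, 1/alpha_dk^(m)) + (1 - h_mk) * delta_0
    h_mk    ~ Bernoulli(pi_k)
    pi_k    ~ Beta(a_pi, b_pi)
    alpha_dk^(m) ~ Gamma(a_alpha, b_alpha)      # shape-rate
    tau_d^(m)    ~ Gamma(a_tau, b_tau_d)        # shape-rate

The beta-Bernoulli layer switches whole loading columns on or off per
view, so a component can be active in any subset of the views; the
spike is an exact point mass at zero (``w`` entries are stored as exact
zeros whenever ``h`` is off).  The Gamma convention is shape-rate
throughout.

This module holds the types, prior/forward sampling and the exact log
joint density; inference lives in :mod:`twingfa.gibbs_sampler`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GFAHyperparams",
    "ViewData",
    "LatentState",
    "LogJointTerms",
    "sample_prior",
    "generate_from_state",
    "log_joint",
]


class ModelError(ValueError):
    """Raised when a state or dataset violates a model invariant."""


@dataclass
class GFAHyperparams:
    """Prior parameters of the GFA model.

    Parameters
    ----------
    K
        Number of latent components (upper bound; unused components
        empty out via the beta-Bernoulli layer).
    a_pi, b_pi
        Beta prior on the per-component inclusion probability ``pi_k``.
        The flat default (1, 1) is uninformative about sparsity.
    a_alpha, b_alpha
        Gamma(shape, rate) ARD prior on slab precisions; the vague
        default ``1e-3`` lets loading scales adapt per variable.
    a_tau
        Gamma shape of the noise-precision prior.  Larger values make
        the prior more informative around its target.
    noise_target
        Prior-mean residual variance as a fraction of the (observed)
        column variance.  The rate is set per column as
        ``b_tau = noise_target * (a_tau - 1) * col_var`` so that the
        prior mean of ``1/tau`` equals ``noise_target * col_var``.
    """

    K: int = 40
    a_pi: float = 1.0
    b_pi: float = 1.0
    a_alpha: float = 1e-3
    b_alpha: float = 1e-3
    a_tau: float = 14.0
    noise_target: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ModelError(f"K must be a positive integer, got {self.K}")
        for name in ("a_pi", "b_pi", "a_alpha", "b_alpha", "a_tau"):
            if getattr(self, name) <= 0:
                raise ModelError(f"{name} must be > 0")
        if not 0 < self.noise_target < 1:
            raise ModelError("noise_target must lie in (0, 1)")
        if self.a_tau <= 1:
            raise ModelError("a_tau must exceed 1 for the noise target to define a prior mean")

    def tau_rate(self, col_var: float | np.ndarray = 1.0) -> float | np.ndarray:
        """Gamma rate of the noise-precision prior for columns of variance ``col_var``."""
        return self.noise_target * (self.a_tau - 1.0) * col_var


@dataclass
class ViewData:
    """One observed data view: N samples x D variables, with missing entries.

    ``X`` stores missing entries as NaN; ``mask`` is True where observed.
    A NaN under a True mask entry is an error (data corruption rather
    than declared missingness).
    """

    X: np.ndarray
    name: str = ""
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    var_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] < 1:
            raise ModelError(f"view {self.name!r}: X must be a 2-D matrix with >= 1 column")
        if self.mask is None:
            self.mask = ~np.isnan(self.X)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.X.shape:
                raise ModelError(f"view {self.name!r}: mask shape mismatch")
            if np.isnan(self.X[self.mask]).any():
                raise ModelError(
                    f"view {self.name!r}: NaN present outside the missing mask"
                )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_vars(self) -> int:
        return self.X.shape[1]

    @property
    def fully_observed(self) -> bool:
        return bool(self.mask.all())

    def filled(self, value: float = 0.0) -> np.ndarray:
        """X with missing entries replaced by ``value`` (for masked algebra)."""
        return np.where(self.mask, self.X, value)

    def observed_col_var(self, ddof: int = 1) -> np.ndarray:
        """Per-column sample variance over observed entries."""
        out = np.empty(self.n_vars)
        for d in range(self.n_vars):
            col = self.X[self.mask[:, d], d]
            out[d] = np.var(col, ddof=ddof) if col.size > ddof else np.nan
        return out


@dataclass
class LatentState:
    """One complete draw of all latent variables.

    Invariant: ``W[m][:, k] == 0`` exactly where ``H[m, k] == 0``.
    """

    Z: np.ndarray                 # N x K
    W: list[np.ndarray]           # per view, D_m x K
    H: np.ndarray                 # M x K in {0, 1}
    pi: np.ndarray                # K, in (0, 1)
    alpha: list[np.ndarray]       # per view, D_m x K, > 0
    tau: list[np.ndarray]         # per view, D_m, > 0

    @property
    def n_views(self) -> int:
        return len(self.W)

    @property
    def n_components(self) -> int:
        return self.Z.shape[1]

    @property
    def n_samples(self) -> int:
        return self.Z.shape[0]

    def validate(self) -> None:
        M, K = self.H.shape
        if len(self.W) != M or len(self.alpha) != M or len(self.tau) != M:
            raise ModelError("per-view lists must all have length M")
        if self.Z.shape[1] != K or self.pi.shape != (K,):
            raise ModelError("component dimension mismatch")
        if not np.all((self.pi > 0) & (self.pi < 1)):
            raise ModelError("pi entries must lie in (0, 1)")
        for m in range(M):
            if np.any(self.alpha[m] <= 0) or np.any(self.tau[m] <= 0):
                raise ModelError(f"view {m}: alpha and tau must be > 0")
            off = self.H[m] == 0
            if off.any() and np.any(self.W[m][:, off] != 0.0):
                raise ModelError(
                    f"view {m}: nonzero loadings in a column whose indicator is off"
                )

    def copy(self) -> "LatentState":
        return LatentState(
            Z=self.Z.copy(),
            W=[w.copy() for w in self.W],
            H=self.H.copy(),
            pi=self.pi.copy(),
            alpha=[a.copy() for a in self.alpha],
            tau=[t.copy() for t in self.tau],
        )


def sample_prior(
    hyper: GFAHyperparams,
    n_samples: int,
    dims: Sequence[int],
    rng: np.random.Generator,
    col_vars: Sequence[np.ndarray] | None = None,
) -> LatentState:
    """Draw a complete latent state from the prior hierarchy.

    ``col_vars`` optionally gives the per-column data variances used to
    anchor the informative noise prior (defaults to 1, i.e. columns
    scaled to unit variance).
    """
    if n_samples < 1 or any(d < 1 for d in dims):
        raise ModelError("dimensions must be positive")
    M, K = len(dims), hyper.K
    pi = rng.beta(hyper.a_pi, hyper.b_pi, size=K)
    H = (rng.random((M, K)) < pi).astype(np.int8)
    alpha, W, tau = [], [], []
    for m, D in enumerate(dims):
        # max() guards the underflow of vague Gamma shapes to exact zero
        a = np.maximum(
            rng.gamma(hyper.a_alpha, 1.0 / hyper.b_alpha, size=(D, K)), 1e-290
        )
        w = rng.standard_normal((D, K)) / np.sqrt(a)
        w[:, H[m] == 0] = 0.0
        cv = 1.0 if col_vars is None else np.asarray(col_vars[m], dtype=float)
        b_tau = hyper.tau_rate(cv)
        t = rng.gamma(hyper.a_tau, 1.0 / (b_tau * np.ones(D)))
        alpha.append(a)
        W.append(w)
        tau.append(t)
    Z = rng.standard_normal((n_samples, K))
    return LatentState(Z=Z, W=W, H=H, pi=pi, alpha=alpha, tau=tau)


def generate_from_state(
    state: LatentState,
    rng: np.random.Generator,
    names: Sequence[str] | None = None,
) -> list[ViewData]:
    """Generate one dataset per view from ``x ~ N(W z, diag(1/tau))``."""
    views = []
    for m in range(state.n_views):
        mean = state.Z @ state.W[m].T
        noise = rng.standard_normal(mean.shape) / np.sqrt(state.tau[m])
        name = names[m] if names is not None else f"view{m}"
        views.append(ViewData(X=mean + noise, name=name))
    return views


@dataclass
class LogJointTerms:
    """Additive decomposition of the log joint density."""

    likelihood: float
    z: float
    w: float
    h: float
    pi: float
    alpha: float
    tau: float

    @property
    def total(self) -> float:
        return (
            self.likelihood + self.z + self.w + self.h + self.pi + self.alpha + self.tau
        )


def log_joint(
    state: LatentState,
    views: Sequence[ViewData],
    hyper: GFAHyperparams,
    col_vars: Sequence[np.ndarray] | None = None,
) -> LogJointTerms:
    """Exact log joint density of (data, latents) under the model.

    Missing cells contribute no likelihood term (ignorable
    missingness).  The spike contributes through the discrete ``h``
    term only; slab densities are evaluated only where ``h = 1``.
    ``alpha`` carries its Gamma prior for every entry, matching a
    sampler that refreshes spiked precisions from the prior.
    """
    state.validate()
    LOG2PI = np.log(2.0 * np.pi)

    ll = 0.0
    tau_term = 0.0
    for m, view in enumerate(views):
        pred = state.Z @ state.W[m].T
        resid2 = np.where(view.mask, (view.filled() - pred) ** 2, 0.0)
        tau = state.tau[m]
        n_obs = view.mask.sum(axis=0)
        ll += 0.5 * float(
            np.sum(n_obs * (np.log(tau) - LOG2PI)) - np.sum(resid2 @ tau)
        )
        cv = 1.0 if col_vars is None else np.asarray(col_vars[m], dtype=float)
        b_tau = hyper.tau_rate(cv) * np.ones_like(tau)
        tau_term += float(
            np.sum(stats.gamma.logpdf(tau, hyper.a_tau, scale=1.0 / b_tau))
        )

    z_term = float(np.sum(stats.norm.logpdf(state.Z)))

    w_term = 0.0
    h_term = 0.0
    alpha_term = 0.0
    for m in range(state.n_views):
        on = state.H[m] == 1
        if on.any():
            a_on = state.alpha[m][:, on]
            w_on = state.W[m][:, on]
            w_term += 0.5 * float(np.sum(np.log(a_on) - LOG2PI - a_on * w_on**2))
        h_term += float(
            np.sum(np.where(state.H[m] == 1, np.log(state.pi), np.log1p(-state.pi)))
        )
        alpha_term += float(
            np.sum(
                stats.gamma.logpdf(
                    state.alpha[m], hyper.a_alpha, scale=1.0 / hyper.b_alpha
                )
            )
        )

    pi_term = float(np.sum(stats.beta.logpdf(state.pi, hyper.a_pi, hyper.b_pi)))

    return LogJointTerms(
        likelihood=ll,
        z=z_term,
        w=w_term,
        h=h_term,
        pi=pi_term,
        alpha=alpha_term,
        tau=tau_term,
    )
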