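"""Conditional-distribution tests for the Gibbs sampler.

Each full conditional is checked against its closed form, a quadrature
oracle, or Monte-Carlo moments of repeated draws — all independent of
the sampler's own algebra.
"""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from twingfa.gfa_model import (
    GFAHyperparams,
    LatentState,
    ModelError,
    ViewData,
    generate_from_state,
    sample_prior,
)
from twingfa.gibbs_sampler import (
    ChainConfig,
    gibbs_sweep,
    run_chain,
    sample_Wh_conditional,
    sample_Z_conditional,
    sample_alpha_conditional,
    sample_pi_conditional,
    sample_tau_conditional,
)

HYPER = GFAHyperparams(K=1, a_alpha=2.0, b_alpha=2.0, a_tau=3.0, noise_target=1 / 3)


def single_state(w, tau, N=1, pi=0.5, alpha=1.0, K=1):
    return LatentState(
        Z=np.zeros((N, K)),
        W=[np.full((1, K), float(w))],
        H=np.ones((1, K), dtype=np.int8),
        pi=np.full(K, pi),
        alpha=[np.full((1, K), float(alpha))],
        tau=[np.array([float(tau)])],
    )


class TestZConditional:
    def test_zero_loadings_give_prior(self):
        state = single_state(w=0.0, tau=1.0, N=3000)
        state.H[:] = 1
        views = [ViewData(X=np.random.default_rng(0).normal(size=(3000, 1)), name="v")]
        Z = sample_Z_conditional(state, views, np.random.default_rng(1))
        assert abs(Z.mean()) < 3 / math.sqrt(3000)
        assert abs(Z.var(ddof=1) - 1.0) < 3 * math.sqrt(2 / 2999)

    def test_scalar_conjugate_arithmetic(self):
        """w=1, tau=1, x=2: posterior N(1, 1/2)."""
        state = single_state(w=1.0, tau=1.0)
        views = [ViewData(X=np.array([[2.0]]), name="v")]
        rng = np.random.default_rng(2)
        draws = np.array(
            [sample_Z_conditional(state, views, rng)[0, 0] for _ in range(20000)]
        )
        assert draws.mean() == pytest.approx(1.0, abs=3 * math.sqrt(0.5 / 20000))
        assert draws.var(ddof=1) == pytest.approx(0.5, rel=0.05)

    def test_multiview_moments_match_analytic(self):
        """3 views with missing cells: empirical mean/cov of draws vs
        the closed-form conditional, within Monte-Carlo error."""
        rng = np.random.default_rng(3)
        K, N = 2, 2
        dims = [2, 3, 1]
        hyper = GFAHyperparams(K=K, a_alpha=2.0, b_alpha=2.0)
        state = sample_prior(hyper, N, dims, rng)
        state.H[:] = 1
        for m, D in enumerate(dims):
            state.W[m] = rng.standard_normal((D, K))
        views = generate_from_state(state, rng)
        views[1].X[0, 1] = np.nan
        views[1] = ViewData(X=views[1].X, name="v1")

        # analytic conditional for sample 0
        lam = np.eye(K)
        rhs = np.zeros(K)
        for m in range(3):
            for d in range(dims[m]):
                if np.isfinite(views[m].X[0, d]):
                    w = state.W[m][d]
                    lam += state.tau[m][d] * np.outer(w, w)
                    rhs += state.tau[m][d] * w * views[m].X[0, d]
        cov = np.linalg.inv(lam)
        mu = cov @ rhs

        n_draws = 100000
        draws = np.empty((n_draws, K))
        rng2 = np.random.default_rng(4)
        for i in range(n_draws):
            draws[i] = sample_Z_conditional(state, views, rng2)[0]
        se = np.sqrt(np.diag(cov) / n_draws)
        assert np.all(np.abs(draws.mean(0) - mu) < 3 * se)
        assert np.allclose(np.cov(draws.T), cov, atol=4 * cov.max() / math.sqrt(n_draws))


class TestWhConditional:
    def test_pi_degeneracies(self):
        state = single_state(w=1.0, tau=1.0, N=3, pi=0.0)
        views = [ViewData(X=np.ones((3, 1)), name="v")]
        rng = np.random.default_rng(5)
        h, w = sample_Wh_conditional(state, views, 0, 0, rng)
        assert h == 0 and np.all(w == 0.0)
        state.pi[:] = 1.0
        h, w = sample_Wh_conditional(state, views, 0, 0, rng)
        assert h == 1 and np.all(w != 0.0)

    def test_inclusion_probability_matches_quadrature(self):
        """N=3, D=1, K=1: p(h=1 | rest) against numerical integration
        of the slab weight."""
        rng = np.random.default_rng(6)
        z = np.array([0.8, -1.1, 0.3])
        x = np.array([1.2, -1.9, 0.1])
        tau, alpha, pi = 2.0, 1.5, 0.4
        state = LatentState(
            Z=z[:, None],
            W=[np.array([[0.7]])],
            H=np.ones((1, 1), dtype=np.int8),
            pi=np.array([pi]),
            alpha=[np.array([[alpha]])],
            tau=[np.array([tau])],
        )
        views = [ViewData(X=x[:, None], name="v")]

        def lik_given_w(w):
            return np.prod(stats.norm.pdf(x, w * z, 1 / math.sqrt(tau)))

        ml1, _ = integrate.quad(
            lambda w: lik_given_w(w) * stats.norm.pdf(w, 0, 1 / math.sqrt(alpha)),
            -np.inf,
            np.inf,
            epsabs=1e-13,
        )
        ml0 = lik_given_w(0.0)
        p_true = pi * ml1 / (pi * ml1 + (1 - pi) * ml0)

        n = 200000
        hits = sum(
            sample_Wh_conditional(state, views, 0, 0, rng)[0] for _ in range(n)
        )
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert abs(hits / n - p_true) < 4 * se

    def test_weight_conditional_given_inclusion(self):
        """With pi=1 the weight draw is N(b/lam, 1/lam)."""
        rng = np.random.default_rng(7)
        z = np.array([1.0, -2.0, 0.5, 1.5])
        x = np.array([0.9, -2.2, 0.6, 1.2])
        tau, alpha = 3.0, 2.0
        state = LatentState(
            Z=z[:, None],
            W=[np.array([[0.0]])],
            H=np.ones((1, 1), dtype=np.int8),
            pi=np.array([1.0]),
            alpha=[np.array([[alpha]])],
            tau=[np.array([tau])],
        )
        views = [ViewData(X=x[:, None], name="v")]
        lam = alpha + tau * np.sum(z**2)
        mu = tau * np.sum(z * x) / lam
        draws = np.array(
            [sample_Wh_conditional(state, views, 0, 0, rng)[1][0] for _ in range(20000)]
        )
        assert draws.mean() == pytest.approx(mu, abs=4 * math.sqrt(1 / lam / 20000))
        assert draws.var(ddof=1) == pytest.approx(1 / lam, rel=0.06)


class TestPiConditional:
    def test_conjugate_counting(self):
        """M=5, sum h = 2, a=b=1: Beta(3, 4), mean 3/7."""
        state = LatentState(
            Z=np.zeros((2, 1)),
            W=[np.zeros((1, 1))] * 5,
            H=np.array([[1], [1], [0], [0], [0]], dtype=np.int8),
            pi=np.array([0.5]),
            alpha=[np.ones((1, 1))] * 5,
            tau=[np.ones(1)] * 5,
        )
        hyper = GFAHyperparams(K=1, a_pi=1.0, b_pi=1.0)
        rng = np.random.default_rng(8)
        draws = np.array([sample_pi_conditional(state, hyper, rng)[0] for _ in range(20000)])
        mean, var = 3 / 7, (3 * 4) / (49 * 8)
        assert draws.mean() == pytest.approx(mean, abs=4 * math.sqrt(var / 20000))
        assert draws.var(ddof=1) == pytest.approx(var, rel=0.08)

    def test_all_off_boundary(self):
        state = LatentState(
            Z=np.zeros((2, 1)),
            W=[np.zeros((1, 1))] * 3,
            H=np.zeros((3, 1), dtype=np.int8),
            pi=np.array([0.5]),
            alpha=[np.ones((1, 1))] * 3,
            tau=[np.ones(1)] * 3,
        )
        hyper = GFAHyperparams(K=1, a_pi=2.0, b_pi=3.0)
        rng = np.random.default_rng(9)
        draws = np.array([sample_pi_conditional(state, hyper, rng)[0] for _ in range(20000)])
        assert draws.mean() == pytest.approx(2 / 8, abs=0.01)  # Beta(2, 3+3)


class TestAlphaConditional:
    def test_zero_weight_with_h_on(self):
        state = single_state(w=0.0, tau=1.0)
        hyper = GFAHyperparams(K=1, a_alpha=2.0, b_alpha=3.0)
        rng = np.random.default_rng(10)
        draws = np.array(
            [sample_alpha_conditional(state, hyper, rng)[0][0, 0] for _ in range(20000)]
        )
        # Gamma(2.5, 3): mean 2.5/3
        assert draws.mean() == pytest.approx(2.5 / 3, rel=0.03)

    def test_h_off_refreshes_from_prior(self):
        state = single_state(w=0.0, tau=1.0)
        state.H[0, 0] = 0
        hyper = GFAHyperparams(K=1, a_alpha=2.0, b_alpha=3.0)
        rng = np.random.default_rng(11)
        draws = np.array(
            [sample_alpha_conditional(state, hyper, rng)[0][0, 0] for _ in range(4000)]
        )
        ks = stats.kstest(draws, stats.gamma(2.0, scale=1 / 3.0).cdf)
        assert ks.pvalue > 0.01

    def test_larger_weight_shrinks_alpha(self):
        hyper = GFAHyperparams(K=1, a_alpha=2.0, b_alpha=2.0)
        rng = np.random.default_rng(12)
        means = []
        for w in (0.1, 3.0):
            state = single_state(w=w, tau=1.0)
            d = np.array(
                [sample_alpha_conditional(state, hyper, rng)[0][0, 0] for _ in range(3000)]
            )
            means.append(d.mean())
        assert means[1] < means[0]


class TestTauConditional:
    def test_zero_residuals_conjugate_shape(self):
        """Perfect fit with n_obs=10: Gamma(a_tau + 5, b_tau)."""
        rng = np.random.default_rng(13)
        z = rng.standard_normal((10, 1))
        state = LatentState(
            Z=z,
            W=[np.array([[2.0]])],
            H=np.ones((1, 1), dtype=np.int8),
            pi=np.array([0.5]),
            alpha=[np.ones((1, 1))],
            tau=[np.ones(1)],
        )
        views = [ViewData(X=2.0 * z, name="v")]
        hyper = GFAHyperparams(K=1, a_tau=3.0, noise_target=0.5)
        b_tau = hyper.tau_rate(1.0)
        draws = np.array(
            [
                sample_tau_conditional(state, views, hyper, rng)[0][0]
                for _ in range(20000)
            ]
        )
        mean = (3.0 + 5.0) / b_tau
        sd = math.sqrt(8.0) / b_tau
        assert draws.mean() == pytest.approx(mean, abs=4 * sd / math.sqrt(20000))

    def test_all_missing_gives_prior(self):
        state = single_state(w=1.0, tau=1.0, N=4)
        X = np.full((4, 1), np.nan)
        views = [ViewData(X=X, name="v")]
        hyper = GFAHyperparams(K=1, a_tau=5.0, noise_target=0.25)
        rng = np.random.default_rng(14)
        draws = np.array(
            [sample_tau_conditional(state, views, hyper, rng)[0][0] for _ in range(4000)]
        )
        ks = stats.kstest(draws, stats.gamma(5.0, scale=1 / hyper.tau_rate(1.0)).cdf)
        assert ks.pvalue > 0.01

    def test_moment_check(self):
        rng = np.random.default_rng(15)
        state = single_state(w=1.5, tau=2.0, N=6)
        state.Z = rng.standard_normal((6, 1))
        views = [ViewData(X=rng.standard_normal((6, 1)), name="v")]
        hyper = GFAHyperparams(K=1, a_tau=4.0, noise_target=0.5)
        ssr = float(np.sum((views[0].X - state.Z * 1.5) ** 2))
        shape, rate = 4.0 + 3.0, hyper.tau_rate(1.0) + ssr / 2
        draws = np.array(
            [sample_tau_conditional(state, views, hyper, rng)[0][0] for _ in range(20000)]
        )
        se = math.sqrt(shape) / rate / math.sqrt(20000)
        assert draws.mean() == pytest.approx(shape / rate, abs=4 * se)


class TestRunChain:
    def test_retained_draw_count_default_protocol(self):
        cfg = ChainConfig()
        assert cfg.n_iter == 2000 and cfg.burnin_frac == 0.9
        assert cfg.n_retained == 200

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(16)
        views = [ViewData(X=rng.standard_normal((10, 4)), name="a")]
        hyper = GFAHyperparams(K=3, a_alpha=2.0, b_alpha=2.0)
        p1 = run_chain(views, hyper, ChainConfig(n_iter=60, burnin_frac=0.5, seed=42))
        p2 = run_chain(views, hyper, ChainConfig(n_iter=60, burnin_frac=0.5, seed=42))
        np.testing.assert_array_equal(p1.z_draws, p2.z_draws)
        np.testing.assert_array_equal(p1.h_draws, p2.h_draws)
        np.testing.assert_array_equal(p1.w_mean[0], p2.w_mean[0])

    def test_nan_outside_mask_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        mask = np.ones((4, 2), dtype=bool)
        with pytest.raises(ModelError, match="mask"):
            ViewData(X=X, mask=mask, name="v")

    def test_variable_permutation_equivariance(self):
        """Permuting variables within a view permutes the (h, w)
        conditional parameters identically: the weight conditional's
        mean permutes and the inclusion probability is unchanged."""
        rng = np.random.default_rng(17)
        hyper = GFAHyperparams(K=2, a_alpha=2.0, b_alpha=2.0)
        state = sample_prior(hyper, 10, [5], rng)
        state.H[:] = 1
        state.pi[:] = 1.0  # forces h=1 so the draw exposes mean + noise
        views = [ViewData(X=rng.standard_normal((10, 5)), name="a")]
        perm = [4, 2, 0, 1, 3]
        state_p = state.copy()
        state_p.W = [state.W[0][perm]]
        state_p.alpha = [state.alpha[0][perm]]
        state_p.tau = [state.tau[0][perm]]
        views_p = [ViewData(X=views[0].X[:, perm], name="a")]

        # average many draws: the noise cancels, the means must permute
        n = 4000
        rng_a, rng_b = np.random.default_rng(1), np.random.default_rng(1)
        wa = np.mean(
            [sample_Wh_conditional(state, views, 0, 0, rng_a)[1] for _ in range(n)],
            axis=0,
        )
        wb = np.mean(
            [sample_Wh_conditional(state_p, views_p, 0, 0, rng_b)[1] for _ in range(n)],
            axis=0,
        )
        np.testing.assert_allclose(wa[perm], wb, atol=0.05)

    def test_missing_cells_excluded_not_imputed(self):
        """A chain on data with masked cells runs and the posterior is
        finite; the log-joint trace is monotone-free but finite."""
        rng = np.random.default_rng(18)
        X = rng.standard_normal((15, 6))
        X[rng.random((15, 6)) < 0.2] = np.nan
        hyper = GFAHyperparams(K=3, a_alpha=2.0, b_alpha=2.0)
        post = run_chain([ViewData(X=X, name="a")], hyper,
                         ChainConfig(n_iter=100, burnin_frac=0.5, seed=1))
        assert np.isfinite(post.log_joint_trace).all()
        assert np.isfinite(post.z_mean).all()
        assert np.all((post.activity >= 0) & (post.activity <= 1))


class TestSweepInternalConsistency:
    def test_sweep_matches_per_block_functions(self):
        """The optimized sweep's residual bookkeeping must agree with
        the direct per-block conditionals: identical rng streams on
        identical states yield identical draws for the (h, w) blocks."""
        rng = np.random.default_rng(19)
        hyper = GFAHyperparams(K=2, a_alpha=2.0, b_alpha=2.0)
        state = sample_prior(hyper, 8, [3, 4], rng)
        views = generate_from_state(state, rng)
        views[0].X[1, 2] = np.nan
        views[0] = ViewData(X=views[0].X, name="view0")

        state_a = state.copy()
        rng_a = np.random.default_rng(99)
        state_a.Z = sample_Z_conditional(state_a, views, rng_a)
        draws_direct = []
        for m in range(2):
            for k in range(hyper.K):
                h, w = sample_Wh_conditional(state_a, views, m, k, rng_a)
                state_a.H[m, k] = h
                state_a.W[m][:, k] = w
                draws_direct.append((h, w.copy()))

        state_b = state.copy()
        rng_b = np.random.default_rng(99)
        gibbs_sweep(state_b, views, hyper, rng_b)
        i = 0
        for m in range(2):
            for k in range(hyper.K):
                h, w = draws_direct[i]
                assert state_b.H[m, k] == h
                np.testing.assert_allclose(state_b.W[m][:, k], w, rtol=1e-10, atol=1e-12)
                i += 1
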