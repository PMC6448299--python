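import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest, norm

from sparsemix import (component_loglik, draw_params_posterior, make_kernel,
                       negbin_rho_logprior, relabel_functional,
                       update_shared_hyper)
from sparsemix.kernels import (NegBinGlmKernel, PoissonGlmKernel,
                               SkewNormalKernel, SkewTKernel, negbin_rho_cdf,
                               sample_rho_prior)


class TestComponentLoglik:
    def test_poisson_at_zero(self):
        assert component_loglik("poisson", 0, {"mu": 1.0}) == pytest.approx(-1.0)

    def test_skew_normal_reduces_to_normal_at_zero_skewness(self):
        val = component_loglik("skew_normal", 0.0,
                               {"xi": 0.0, "omega": 1.0, "alpha": 0.0})
        assert val == pytest.approx(norm.logpdf(0.0), abs=1e-12)

    def test_categorical_product_of_class_probabilities(self):
        # class-2 modal categories of the fear data: one obs (M=2, C=1, F=1)
        theta = {"pi": [(0.1, 0.573, 0.2, 0.127), (0.679, 0.2, 0.121),
                        (0.629, 0.3, 0.071)]}
        val = component_loglik("lca", [1, 0, 0], theta)
        assert val == pytest.approx(math.log(0.573 * 0.679 * 0.629))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            component_loglik("lca", [5, 0, 0], {"pi": [(0.5, 0.5)] * 3})
        with pytest.raises(ValueError):
            component_loglik("poisson", -1, {"mu": 2.0})

    def test_densities_normalize(self):
        # count kernels: sum over 0..large; continuous kernels: quadrature
        mu = 3.7
        s = sum(math.exp(component_loglik("poisson", y, {"mu": mu}))
                for y in range(200))
        assert s == pytest.approx(1.0, abs=1e-9)
        x = np.ones((1, 1))
        nb = sum(math.exp(component_loglik("negbin_glm", (y, [1.0]),
                                           {"beta": [math.log(mu)], "rho": 2.5}))
                 for y in range(500))
        assert nb == pytest.approx(1.0, abs=1e-6)
        for theta in ({"xi": 0.5, "omega": 2.0, "alpha": -3.0},):
            val, _ = quad(lambda yy: math.exp(
                component_loglik("skew_normal", yy, theta)), -40, 40, limit=200)
            assert val == pytest.approx(1.0, abs=1e-6)
        val, _ = quad(lambda yy: math.exp(component_loglik(
            "skew_t", yy, {"xi": 0.5, "omega": 2.0, "alpha": 2.0, "nu": 5.0})),
            -200, 200, limit=400)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_skew_normal_matches_normal_on_grid(self):
        grid = np.linspace(-6, 6, 101)
        sn = np.array([component_loglik("skew_normal", g,
                                        {"xi": 0.0, "omega": 1.0, "alpha": 0.0})
                       for g in grid])
        np.testing.assert_allclose(sn, norm.logpdf(grid), atol=1e-12)


class TestConjugatePosteriors:
    def test_poisson_posterior_moments(self):
        # subset y=(2,3), a0=0.1, b0=0.5 -> Gamma(5.1, 2.5), mean 2.04
        rng = np.random.default_rng(0)
        draws = np.array([draw_params_posterior(
            "poisson", [2, 3], {"a0": 0.1, "b0": 0.5}, rng)["mu"]
            for _ in range(100_000)])
        mean, var = 5.1 / 2.5, 5.1 / 2.5 ** 2
        assert abs(draws.mean() - mean) < 4 * math.sqrt(var / draws.size)

    def test_categorical_posterior_mean(self):
        # counts (4,0,1) with g0=1 -> Dirichlet(5,1,2), mean (5/8,1/8,2/8)
        rng = np.random.default_rng(1)
        y = np.array([[0]] * 4 + [[2]])
        draws = np.stack([draw_params_posterior(
            "lca", y, {"n_categories": [3], "g0": 1.0}, rng)["pi"][0]
            for _ in range(100_000)])
        conc = np.array([5.0, 1.0, 2.0])
        mean = conc / 8.0
        var = conc * (8 - conc) / (64 * 9)
        assert np.all(np.abs(draws.mean(axis=0) - mean)
                      < 4 * np.sqrt(var / draws.shape[0]))

    def test_empty_subset_draws_from_prior(self):
        rng = np.random.default_rng(2)
        draws = np.stack([draw_params_posterior(
            "lca", np.empty((0, 1), dtype=int),
            {"n_categories": [3], "g0": 1.0}, rng)["pi"][0]
            for _ in range(50_000)])
        # Dirichlet(1,1,1): uniform on the simplex, mean 1/3, var 1/18
        assert np.all(np.abs(draws.mean(axis=0) - 1 / 3)
                      < 4 * math.sqrt(1 / 18 / draws.shape[0]))


class TestSharedHyper:
    def test_poisson_b0_conditional(self):
        # K=1, mu=1, a0=0.1, g0=0.5, G0=1 -> b0 ~ Gamma(0.6, 2.0)
        rng = np.random.default_rng(3)
        draws = np.array([update_shared_hyper(
            "poisson", [1.0], {"a0": 0.1, "g0": 0.5, "G0": 1.0}, rng)["b0"]
            for _ in range(100_000)])
        mean, var = 0.6 / 2.0, 0.6 / 4.0
        assert abs(draws.mean() - mean) < 4 * math.sqrt(var / draws.size)

    def test_limit_is_prior_shape(self):
        rng = np.random.default_rng(4)
        draws = np.array([update_shared_hyper(
            "poisson", [1e-12, 1e-12], {"a0": 0.1, "g0": 0.5, "G0": 1.0},
            rng)["b0"] for _ in range(50_000)])
        mean = (0.5 + 2 * 0.1) / 1.0
        assert abs(draws.mean() - mean) < 4 * math.sqrt(mean / np.sqrt(draws.size))

    def test_other_kernels_unchanged(self):
        hyper = {"g0": 1.0}
        out = update_shared_hyper("lca", None, hyper, np.random.default_rng(0))
        assert out == hyper


class TestRhoPrior:
    def test_normalization_by_quadrature(self):
        c = 10.0 / (1.0 + math.sqrt(2.0))
        val, _ = quad(lambda r: math.exp(negbin_rho_logprior(r, c)), 0, np.inf,
                      limit=400)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_median_is_ten(self):
        c = 10.0 / (1.0 + math.sqrt(2.0))
        assert negbin_rho_cdf(10.0, c) == pytest.approx(0.5, abs=1e-12)

    def test_density_vanishes_at_limits(self):
        c = 2.0
        assert math.exp(negbin_rho_logprior(1e-12, c)) < 1e-10
        assert math.exp(negbin_rho_logprior(1e12, c)) < 1e-10

    def test_domain_error(self):
        with pytest.raises(ValueError):
            negbin_rho_logprior(-1.0, 2.0)

    def test_inverse_cdf_sampler(self):
        rng = np.random.default_rng(5)
        draws = sample_rho_prior(rng, size=100_000)
        med = np.median(draws)
        assert abs(negbin_rho_cdf(med) - 0.5) < 4 * 0.5 / math.sqrt(draws.size)


class TestRelabelFunctional:
    def test_poisson(self):
        np.testing.assert_allclose(
            relabel_functional("poisson", {"mu": 2.5}), [2.5])

    def test_categorical_dimension(self):
        theta = {"pi": [np.full(4, 0.25), np.full(3, 1 / 3), np.full(3, 1 / 3)]}
        assert relabel_functional("lca", theta).shape == (10,)

    def test_skew_normal_passthrough(self):
        np.testing.assert_allclose(
            relabel_functional("skew_normal",
                               {"xi": 1.0, "omega": 2.0, "alpha": -3.0}),
            [1.0, 2.0, -3.0])


class TestMarkovUpdatesInvariance:
    """The MH/Gibbs parameter updates must leave the complete-data posterior
    invariant; validated against brute-force grid posteriors on tiny data."""

    def test_poisson_glm_intercept_invariance(self):
        y = np.array([0, 1, 1, 2, 3, 0, 1, 2])
        X = np.ones((y.size, 1))
        kern = PoissonGlmKernel(y, X, tau2=4.0)
        rng = np.random.default_rng(6)
        alloc = np.zeros(y.size, dtype=int)
        params = kern.init_params(1, rng, alloc=alloc)
        draws = np.empty(100_000)
        for i in range(draws.size):
            params = kern.update_params(params, alloc, 1, rng,
                                        adapt=i < 2000)
            draws[i] = params[0, 0]
        # grid posterior for beta ~ N(0,4), Poisson likelihood
        grid = np.linspace(-3, 3, 4001)
        logp = (-0.5 * grid ** 2 / 4.0
                + y.sum() * grid - y.size * np.exp(grid))
        cdf = np.cumsum(np.exp(logp - logp.max()))
        cdf /= cdf[-1]
        stat = kstest(draws[2000:],
                      lambda x: np.interp(x, grid, cdf)).statistic
        assert stat < 0.02

    def test_skew_normal_gibbs_invariance(self):
        rng = np.random.default_rng(7)
        delta = 0.8 / math.sqrt(1 + 0.8 ** 2)
        z = np.abs(rng.normal(size=12))
        y = 1.0 + 2.0 * (delta * z
                         + math.sqrt(1 - delta ** 2) * rng.normal(size=12))
        kern = SkewNormalKernel(y, b_xi=0.0, B0=4.0, c0=2.5, C0=1.0)
        params = kern.init_params(1, rng,
                                  alloc=np.zeros(y.size, dtype=int))[0]
        # the augmentation chain is strongly autocorrelated on 12 points, so
        # thin to keep the KS comparison noise below its tolerance
        thin = 10
        ones = np.ones(y.size)
        draws = np.empty(100_000)
        for i in range(draws.size):
            for _ in range(thin):
                params, _ = kern._update_component(y, ones, params, rng)
            draws[i] = params[0]  # xi
        # brute-force grid posterior of xi: integrate psi and sigma2 out
        xi_g = np.linspace(y.min() - 3, y.max() + 3, 80)
        psi_g = np.linspace(-5, 5, 60)
        s2_g = np.exp(np.linspace(math.log(0.05), math.log(30), 60))
        XI, PSI, S2 = np.meshgrid(xi_g, psi_g, s2_g, indexing="ij")
        omega = np.sqrt(S2 + PSI ** 2)
        alpha = PSI / np.sqrt(S2)
        loglik = np.zeros_like(XI)
        for yy in y:
            zz = (yy - XI) / omega
            loglik += (math.log(2.0) - np.log(omega) + norm.logpdf(zz)
                       + norm.logcdf(alpha * zz))
        logpost = (loglik - 0.5 * XI ** 2 / 4.0 - 0.5 * PSI ** 2 / 4.0
                   + (-2.5 - 1.0) * np.log(S2) - 1.0 / S2
                   + np.log(S2))  # jacobian of the log-spaced sigma2 grid
        w = np.exp(logpost - logpost.max())
        marg = w.sum(axis=(1, 2))
        cdf = np.cumsum(marg)
        cdf /= cdf[-1]
        stat = kstest(draws[5000:],
                      lambda x: np.interp(x, xi_g, cdf)).statistic
        assert stat < 0.02

    def test_negbin_degenerate_singleton_does_not_crash(self):
        y = np.array([3])
        X = np.ones((1, 2))
        X[:, 1] = 0.5
        kern = NegBinGlmKernel(y, X)
        rng = np.random.default_rng(8)
        params = kern.init_params(2, rng)
        alloc = np.zeros(1, dtype=int)
        for _ in range(50):
            params = kern.update_params(params, alloc, 2, rng, adapt=True)
        assert np.all(np.isfinite(params))
        assert np.all(params[:, -1] > 0)

    def test_skew_t_update_runs_and_stays_finite(self):
        rng = np.random.default_rng(9)
        y = rng.standard_t(6, size=40) * 1.5 + 2.0
        kern = SkewTKernel(y)
        alloc = np.zeros(y.size, dtype=int)
        params = kern.init_params(2, rng, alloc=alloc)
        for _ in range(100):
            params = kern.update_params(params, alloc, 2, rng, adapt=True)
        assert np.all(np.isfinite(params))
        assert np.all(params[:, 2] > 0) and np.all(params[:, 3] > 0)

    def test_categorical_unobserved_category_safe(self):
        y = np.zeros((5, 1), dtype=int)  # category 2 never observed
        kern = make_kernel("lca", y, {"n_categories": [3], "g0": 1.0})
        rng = np.random.default_rng(10)
        params = kern.update_params(None, np.zeros(5, dtype=int), 2, rng)
        ll = kern.loglik_matrix(params)
        assert np.all(np.isfinite(ll))
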