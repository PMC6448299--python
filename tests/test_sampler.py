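import math

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import kstest

from sparsemix import (PriorConfig, classify_slice, log_partition_prob_dpm,
                       log_partition_prob_sfm, make_kernel, run_mcmc,
                       update_precision)
from sparsemix.priors_weights import StickSet
from sparsemix.sampler import (KAPPA, MixtureState, PrecisionSampler,
                               _slice_kmax)


class TestPartitionProbabilities:
    def test_sfm_hand_example(self):
        # N=2, K=2, e0=1, counts (2,0): 2 * Gamma(2)/Gamma(4) * Gamma(3) = 2/3
        val = log_partition_prob_sfm([2, 0], 1.0, 2)
        assert val == pytest.approx(math.log(2.0 / 3.0))

    def test_dpm_hand_example(self):
        # N=2, alpha=1, one cluster of 2: 1 * Gamma(1)/Gamma(3) * Gamma(2) = 1/2
        assert log_partition_prob_dpm([2], 1.0) == pytest.approx(math.log(0.5))

    @pytest.mark.parametrize("N", [2, 3, 4])
    def test_sfm_normalizes_over_set_partitions(self, N, all_set_partitions):
        for e0, K in [(1.0, 2), (0.7, 3), (4.0, 4)]:
            total = 0.0
            for part in all_set_partitions(range(N)):
                if len(part) > K:
                    continue
                counts = [len(b) for b in part] + [0] * (K - len(part))
                # labeled-component probability divided by the number of
                # labelings of this partition: K!/(K-K+)! already counts them
                total += math.exp(log_partition_prob_sfm(counts, e0, K)) \
                    / (math.factorial(K) / math.factorial(K - len(part)))
            # p(P) = multiplicity * p(one labeling); summing p(P) over set
            # partitions must give 1
            total2 = sum(
                math.exp(log_partition_prob_sfm(
                    [len(b) for b in part] + [0] * (K - len(part)), e0, K))
                for part in all_set_partitions(range(N)) if len(part) <= K)
            assert total2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 3.0])
    def test_dpm_normalizes_over_set_partitions(self, alpha, all_set_partitions):
        for N in (2, 3, 4):
            total = sum(
                math.exp(log_partition_prob_dpm([len(b) for b in part], alpha))
                for part in all_set_partitions(range(N)))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_tiny_e0_matches_high_precision_oracle(self):
        import mpmath

        e0 = 1e-10
        counts = [5, 5, 0, 0]
        val = log_partition_prob_sfm(counts, e0, 4)
        assert math.isfinite(val)
        mp = mpmath.mp
        mp.dps = 50
        e = mpmath.mpf(e0)
        K, N = 4, 10
        ref = (mpmath.log(mpmath.factorial(K) / mpmath.factorial(K - 2))
               + mpmath.loggamma(K * e) - mpmath.loggamma(N + K * e)
               + 2 * (mpmath.loggamma(5 + e) - mpmath.loggamma(e)))
        assert val == pytest.approx(float(ref), rel=1e-8)


class TestPrecisionUpdate:
    def test_fixed_prior_returns_current(self):
        prior = PriorConfig(family="sparse_finite", K=2,
                            precision_prior="fixed", value=4.0)
        out = update_precision([1, 1], 2, "sparse_finite", prior, 4.0,
                               np.random.default_rng(0))
        assert out == 4.0

    def test_mh_matches_quadrature_posterior(self):
        # toy: N=2, K=2, counts (1,1), e0 ~ Gamma(1,1)
        prior = PriorConfig(family="sparse_finite", K=2,
                            precision_prior="gamma", shape=1.0, rate=1.0)
        sampler = PrecisionSampler(prior)
        rng = np.random.default_rng(1)
        counts = np.array([1, 1])
        x = 0.5
        draws = np.empty(100_000)
        for i in range(draws.size):
            x = sampler.step(counts, 2, x, rng, adapt=i < 2000)
            draws[i] = x
        grid = np.linspace(1e-6, 30, 20001)
        logp = np.array([log_partition_prob_sfm(counts, g, 2) for g in grid]) \
            - grid  # Gamma(1,1) prior
        cdf = np.cumsum(np.exp(logp - logp.max()))
        cdf /= cdf[-1]
        stat = kstest(draws[2000:], lambda v: np.interp(v, grid, cdf)).statistic
        assert stat < 0.02

    def test_uniform_prior_respects_bound(self):
        prior = PriorConfig(family="sparse_finite", K=3,
                            precision_prior="uniform", upper=1.5)
        sampler = PrecisionSampler(prior)
        rng = np.random.default_rng(2)
        x = 0.5
        draws = [x := sampler.step(np.array([3, 2, 0]), 3, x, rng)
                 for _ in range(5000)]
        assert max(draws) < 1.5 and min(draws) > 0


class TestClassification:
    def _uniform_kernel_state(self, weights):
        K = len(weights)
        sticks = np.ones(K)  # placeholder; weights passed directly
        return MixtureState(params=np.zeros((K, 1)), sticks=StickSet(sticks),
                            weights=np.asarray(weights, float),
                            alloc=np.zeros(1, dtype=int),
                            counts=np.array([1] + [0] * (K - 1)),
                            precision=1.0)

    def test_sfm_symmetric_classification(self):
        # two components, equal weights, equal likelihoods -> P(S=1) = 1/2
        class Flat:
            def loglik_matrix(self, params):
                return np.zeros((params.shape[0], 1))

        prior = PriorConfig(family="sparse_finite", K=2,
                            precision_prior="fixed", value=1.0)
        state = self._uniform_kernel_state([0.5, 0.5])
        rng = np.random.default_rng(3)
        hits = 0
        n = 100_000
        for _ in range(n):
            new = classify_slice(state, Flat(), "sparse_finite", prior, rng)
            hits += new.alloc[0] == 0
        assert abs(hits / n - 0.5) < 4 * 0.5 / math.sqrt(n)

    def test_sfm_classification_matches_exact_distribution(self):
        class Fixed:
            def loglik_matrix(self, params):
                return np.log(np.array([[0.9], [0.3]]))

        prior = PriorConfig(family="sparse_finite", K=2,
                            precision_prior="fixed", value=1.0)
        state = self._uniform_kernel_state([0.2, 0.8])
        rng = np.random.default_rng(4)
        n = 100_000
        hits = sum(classify_slice(state, Fixed(), "sparse_finite", prior,
                                  rng).alloc[0] == 0 for _ in range(n))
        p = 0.2 * 0.9 / (0.2 * 0.9 + 0.8 * 0.3)
        assert abs(hits / n - p) < 4 * math.sqrt(p * (1 - p) / n)

    def test_dpm_slice_bounds_are_geometric(self):
        xi = (1 - KAPPA) * KAPPA ** (np.arange(1, 6) - 1)
        np.testing.assert_allclose(xi[:3], [0.2, 0.16, 0.128])
        # k_max inverts the bound: u just below xi_k admits exactly k levels
        for k in (1, 3, 7):
            u = (1 - KAPPA) * KAPPA ** (k - 1) * 0.999
            assert _slice_kmax(np.array([u]))[0] == k

    def test_impossible_observation_raises(self):
        class Impossible:
            def loglik_matrix(self, params):
                return np.full((params.shape[0], 1), -np.inf)

        prior = PriorConfig(family="sparse_finite", K=2,
                            precision_prior="fixed", value=1.0)
        state = self._uniform_kernel_state([0.5, 0.5])
        with pytest.raises(FloatingPointError):
            classify_slice(state, Impossible(), "sparse_finite", prior,
                           np.random.default_rng(5))


class TestNewClusterProbabilities:
    """Empirical cluster-birth frequencies must match the closed forms
    e0 (K - K+^{-i}) / (N - 1 + e0 K) for the SFM and alpha / (N - 1 + alpha)
    for the DPM (uniform kernel, parameters held fixed)."""

    def test_sfm_birth_probability(self):
        from sparsemix import sample_sticks_conditional

        rng = np.random.default_rng(6)
        K, e0 = 5, 0.3
        counts_minus = np.array([6, 3, 0, 0, 0])  # K+^{-i} = 2, N-1 = 9
        N = counts_minus.sum() + 1
        prior = PriorConfig(family="sparse_finite", K=K,
                            precision_prior="fixed", value=e0)
        n = 200_000
        hits = 0
        for _ in range(n):
            w = sample_sticks_conditional(counts_minus, prior, e0, rng).weights
            k = rng.choice(K, p=w)
            hits += counts_minus[k] == 0
        expect = e0 * (K - 2) / (N - 1 + e0 * K)
        assert abs(hits / n - expect) < 4 * math.sqrt(expect * (1 - expect) / n)

    def test_dpm_birth_probability(self):
        # The DPM formula alpha/(N-1+alpha) conditions on the partition of
        # the remaining observations only, so it is checked on the running
        # chain: with a uniform kernel the sampler's stationary law is the
        # DP prior, and the frequency that a tagged observation sits in a
        # singleton, given the others' cluster sizes, is the CRP predictive.
        from sparsemix import sample_sticks_conditional
        from sparsemix.priors_weights import StickSet

        class Flat:
            def loglik_matrix(self, params):
                return np.zeros((params.shape[0], self.n))

            def grow(self, params, K_new, rng):
                return np.zeros((K_new, 1))

        rng = np.random.default_rng(7)
        alpha, N = 0.8, 6
        prior = PriorConfig(family="dirichlet_process", K=3,
                            precision_prior="fixed", value=alpha)
        kern = Flat()
        kern.n = N
        alloc = np.zeros(N, dtype=int)
        hits = {}
        for sweep in range(100_000):
            counts = np.bincount(alloc)
            sticks = sample_sticks_conditional(counts, prior, alpha, rng)
            state = MixtureState(np.zeros((counts.size, 1)), sticks,
                                 sticks.weights, alloc, counts, alpha)
            state = classify_slice(state, kern, "dirichlet_process", prior,
                                   rng)
            alloc = state.alloc
            if sweep < 1000 or sweep % 2:
                continue
            others = np.delete(alloc, 0)
            sizes = tuple(sorted(np.bincount(others)[np.bincount(others) > 0],
                                 reverse=True))
            singleton = np.sum(alloc == alloc[0]) == 1
            n_hit, n_tot = hits.get(sizes, (0, 0))
            hits[sizes] = (n_hit + singleton, n_tot + 1)
        expect = alpha / (N - 1 + alpha)
        for sizes in ((3, 2), (5,), (4, 1)):
            n_hit, n_tot = hits[sizes]
            se = math.sqrt(expect * (1 - expect) / n_tot)
            assert abs(n_hit / n_tot - expect) < 4 * se, (sizes, n_hit / n_tot)


class TestRunMcmc:
    def test_seed_determinism(self, lca_small):
        codes, _, design = lca_small
        prior = PriorConfig(family="sparse_finite", K=5,
                            precision_prior="gamma", shape=1.0, rate=100.0,
                            kernel_hyper={"n_categories": design.n_categories})
        t1 = run_mcmc(codes[:40], "lca", prior, n_burnin=50, n_iter=100, seed=9)
        t2 = run_mcmc(codes[:40], "lca", prior, n_burnin=50, n_iter=100, seed=9)
        np.testing.assert_array_equal(t1.alloc, t2.alloc)
        np.testing.assert_array_equal(t1.precision, t2.precision)
        np.testing.assert_array_equal(t1.kplus, t2.kplus)

    def test_single_component_poisson_matches_conjugate_closed_form(self):
        rng = np.random.default_rng(10)
        y = rng.poisson(4.0, size=60)
        b0 = 0.5
        prior = PriorConfig(family="sparse_finite", K=1,
                            precision_prior="fixed", value=1.0,
                            kernel_hyper={"a0": 0.1, "b0_fixed": b0})
        trace = run_mcmc(y, "poisson", prior, n_burnin=500, n_iter=20_000,
                         seed=11)
        assert np.all(trace.kplus == 1)
        mus = np.array([f[0, 0] for f in trace.occ_functional])
        shape, rate = 0.1 + y.sum(), b0 + y.size
        assert abs(mus.mean() - shape / rate) < 4 * math.sqrt(
            shape / rate ** 2 / mus.size) * 3
        assert np.allclose(trace.alloc, 0)

    def test_homogeneous_poisson_recovers_one_cluster(self):
        ok = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            y = rng.poisson(5.0, size=200)
            prior = PriorConfig(family="sparse_finite", K=10,
                                precision_prior="gamma", shape=1.0, rate=200.0)
            trace = run_mcmc(y, "poisson", prior, n_burnin=1000, n_iter=2000,
                             seed=seed)
            vals, freq = np.unique(trace.kplus, return_counts=True)
            ok += vals[np.argmax(freq)] == 1
        assert ok >= 4

    def test_trace_roundtrip_serialization(self, tmp_path, lca_small):
        codes, _, design = lca_small
        prior = PriorConfig(family="sparse_finite", K=4,
                            precision_prior="gamma", shape=1.0, rate=50.0,
                            kernel_hyper={"n_categories": design.n_categories})
        trace = run_mcmc(codes[:30], "lca", prior, n_burnin=20, n_iter=40,
                         seed=12)
        from sparsemix import McmcTrace

        trace.save(str(tmp_path / "trace"))
        back = McmcTrace.load(str(tmp_path / "trace"))
        np.testing.assert_array_equal(back.kplus, trace.kplus)
        np.testing.assert_array_equal(back.alloc, trace.alloc)
        np.testing.assert_allclose(back.occ_weights[0], trace.occ_weights[0])
        assert back.meta["family"] == "sparse_finite"

    def test_dpm_truncation_grows_and_counts_stay_consistent(self):
        rng = np.random.default_rng(13)
        y = np.concatenate([rng.poisson(1.0, 50), rng.poisson(20.0, 50)])
        prior = PriorConfig(family="dirichlet_process", K=5,
                            precision_prior="gamma", shape=2.0, rate=4.0)
        trace = run_mcmc(y, "poisson", prior, n_burnin=200, n_iter=400, seed=14)
        for m in range(len(trace)):
            counts = np.bincount(trace.alloc[m])
            assert int((counts > 0).sum()) == trace.kplus[m]
        pmf_vals, pmf_freq = np.unique(trace.kplus, return_counts=True)
        assert pmf_vals[np.argmax(pmf_freq)] == 2
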