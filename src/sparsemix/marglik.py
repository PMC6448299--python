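"""Marginal likelihoods p(y | K) for standard finite mixtures (e0 fixed).

Three routes:

* exact closed forms at K = 1 for the conjugate kernels (latent class /
  categorical and Poisson);
* full-permutation bridge sampling for K >= 2: the importance density is the
  average of the complete-data posteriors over a subsequence of S0 allocation
  draws, symmetrized over all K! label permutations, combined with the
  posterior draws through the iterative optimal-bridge recursion;
* a brute-force enumeration oracle over all K^N allocations for tiny
  problems, used to validate the bridge estimator in tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .kernels import CategoricalKernel, PoissonKernel
from .sampler import McmcTrace

__all__ = [
    "MarglikResult",
    "lca_marglik_exact_k1",
    "poisson_marglik_exact_k1",
    "bridge_marglik",
    "enumerate_marglik_oracle",
]

PERMUTATION_CAP = 5040  # 7!


@dataclass
class MarglikResult:
    K: int
    log_marglik: float
    se: float
    method: str            # "exact" | "bridge" | "enumeration"
    S0: int | None = None
    n_permutations: int | None = None

    def to_dict(self) -> dict:
        return {"K": self.K, "log_marglik": self.log_marglik, "se": self.se,
                "method": self.method, "S0": self.S0,
                "n_permutations": self.n_permutations}


# ---------------------------------------------------------------------------
# exact K = 1 marginals
# ---------------------------------------------------------------------------

def _dirmult_log_marginal(counts: np.ndarray, g0: float) -> float:
    """log of the Dirichlet-multinomial marginal for one categorical
    variable: Gamma(D g0)/Gamma(N + D g0) * prod_l Gamma(n_l + g0)/Gamma(g0)."""
    counts = np.asarray(counts, dtype=float)
    D, N = counts.size, counts.sum()
    return float(gammaln(D * g0) - gammaln(N + D * g0)
                 + np.sum(gammaln(counts + g0) - gammaln(g0)))


def lca_marglik_exact_k1(y: np.ndarray, n_categories, g0=1.0) -> float:
    """Exact log p(y | K=1) of the latent class model: with one class the
    variables are independent Dirichlet-multinomials."""
    y = np.asarray(y, dtype=int)
    if y.size == 0:
        raise ValueError("empty data")
    D = np.asarray(n_categories, dtype=int)
    g0 = np.broadcast_to(np.asarray(g0, dtype=float), D.shape)
    total = 0.0
    for j, d in enumerate(D):
        counts = np.bincount(y[:, j], minlength=d)
        total += _dirmult_log_marginal(counts, float(g0[j]))
    return total


def _poisson_log_marginal(y_sum: float, n: int, lgamma_y_sum: float,
                          a0: float, b0: float) -> float:
    """Closed-form log integral of prod Poisson(y_i | mu) Gamma(mu | a0, b0)."""
    return (gammaln(a0 + y_sum) - gammaln(a0)
            + a0 * math.log(b0) - (a0 + y_sum) * math.log(b0 + n)
            - lgamma_y_sum)


def poisson_marglik_exact_k1(y: np.ndarray, a0: float = 0.1,
                             b0: float | None = None, g0: float = 0.5,
                             G0: float | None = None) -> float:
    """Exact log p(y | K=1) for the Poisson kernel.

    With b0 given the marginal is closed form; under the hierarchical prior
    b0 ~ Gamma(g0, G0) the one remaining integral over b0 is evaluated by
    Gauss-Legendre quadrature on a transformed axis.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty data")
    lg = float(np.sum(gammaln(y + 1.0)))
    if b0 is not None:
        return _poisson_log_marginal(y.sum(), y.size, lg, a0, b0)
    if G0 is None:
        G0 = g0 * float(y.mean()) / a0
    # integrate exp(log m(y | b0) + log Gamma(b0; g0, G0)) db0 via b0 = t/(1-t)
    nodes, wts = np.polynomial.legendre.leggauss(200)
    t = 0.5 * (nodes + 1.0)
    w = 0.5 * wts
    b = t / (1.0 - t)
    jac = 1.0 / (1.0 - t) ** 2
    logint = (np.array([_poisson_log_marginal(y.sum(), y.size, lg, a0, bb)
                        for bb in b])
              + g0 * math.log(G0) - gammaln(g0)
              + (g0 - 1.0) * np.log(b) - G0 * b)
    return float(logsumexp(logint + np.log(w * jac)))


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

def _log_alloc_prior(counts: np.ndarray, e0: float, K: int) -> float:
    """log p(S | e0, K) for one labeled allocation sequence (Dirichlet-
    multinomial without the multinomial coefficient)."""
    N = counts.sum()
    return float(gammaln(K * e0) - gammaln(N + K * e0)
                 + np.sum(gammaln(counts + e0) - gammaln(e0)))


def enumerate_marglik_oracle(data, kernel_id: str, K: int, e0: float,
                             hyper: dict | None = None) -> float:
    """Exact log p(y | K) by summing over all K^N allocations.

    p(y | K) = sum_S p(S | e0, K) prod_k m_k(y_{S=k}) with m_k the conjugate
    component marginal.  Exponential cost; requires K^N <= 1e6.
    """
    hyper = dict(hyper or {})
    if kernel_id == "lca":
        y = np.asarray(data, dtype=int)
        N = y.shape[0]
        D = np.asarray(hyper.get("n_categories", y.max(axis=0) + 1), dtype=int)
        g0 = np.broadcast_to(np.asarray(hyper.get("g0", 1.0), float), D.shape)

        def comp_marg(idx):
            if idx.size == 0:
                return 0.0
            return sum(_dirmult_log_marginal(
                np.bincount(y[idx, j], minlength=d), float(g0[j]))
                for j, d in enumerate(D))
    elif kernel_id == "poisson":
        yv = np.asarray(data, dtype=float)
        N = yv.size
        a0 = hyper.get("a0", 0.1)
        b0 = hyper.get("b0")
        if b0 is None:
            raise ValueError("enumeration oracle needs a fixed b0")
        lgy = gammaln(yv + 1.0)

        def comp_marg(idx):
            if idx.size == 0:
                return 0.0
            return _poisson_log_marginal(yv[idx].sum(), idx.size,
                                         float(lgy[idx].sum()), a0, b0)
    else:
        raise ValueError(f"enumeration oracle not available for {kernel_id!r}")

    if K ** N > 1_000_000:
        raise ValueError("K^N too large for enumeration")
    terms = []
    for S in itertools.product(range(K), repeat=N):
        S = np.asarray(S, dtype=int)
        counts = np.bincount(S, minlength=K)
        lp = _log_alloc_prior(counts, e0, K)
        lp += sum(comp_marg(np.where(S == k)[0]) for k in range(K))
        terms.append(lp)
    return float(logsumexp(np.asarray(terms)))


# ---------------------------------------------------------------------------
# full-permutation bridge sampling
# ---------------------------------------------------------------------------

class _LcaBridgeAdapter:
    """Closed-form pieces of the latent class model used by the bridge."""

    def __init__(self, kernel: CategoricalKernel, K: int, e0: float):
        self.kern = kernel
        self.K, self.e0 = K, e0
        self.d = int(kernel.D.sum())

    def posterior_blocks(self, alloc):
        """Dirichlet concentrations of the complete-data posterior given S:
        (eta_conc (K,), comp_conc (K, d))."""
        counts = np.bincount(alloc, minlength=self.K).astype(float)
        conc = np.tile(np.repeat(self.kern.g0, self.kern.D), (self.K, 1))
        for j in range(self.kern.D.size):
            np.add.at(conc, (alloc, self.kern._flat_idx[:, j]), 1.0)
        return self.e0 + counts, conc

    def comp_logconst(self, conc):
        """(K,) log normalizing constants of the per-component Dirichlet
        blocks."""
        out = np.zeros(conc.shape[0])
        off = self.kern.offsets
        for j in range(self.kern.D.size):
            sl = slice(off[j], off[j + 1])
            out += gammaln(conc[:, sl].sum(axis=1)) - gammaln(conc[:, sl]).sum(axis=1)
        return out

    def comp_features(self, theta):
        """T(theta_k) such that log q-block = coef . T + const; here log theta."""
        return np.log(np.maximum(theta, 1e-300))

    def comp_coef(self, conc):
        return conc - 1.0

    def sample_component(self, conc, rng):
        """One draw of the K components' packed parameters given (K, d) conc."""
        g = np.maximum(rng.gamma(np.maximum(conc, 1e-12)), 1e-300)
        off = self.kern.offsets
        for j in range(self.kern.D.size):
            sl = slice(off[j], off[j + 1])
            g[:, sl] /= g[:, sl].sum(axis=1, keepdims=True)
        return g

    def log_prior_theta(self, theta):
        """(P,) summed log prior density of all K components."""
        P = theta.shape[0]
        flat = theta.reshape(P * self.K, self.d)
        return self.kern.log_prior_density(flat).reshape(P, self.K).sum(axis=1)

    def loglik(self, theta, eta):
        """(P,) mixture log likelihood of the data."""
        P = theta.shape[0]
        logp = np.zeros((P, self.K, self.kern.n_obs))
        lt = np.log(np.maximum(theta, 1e-300))
        for j in range(self.kern.D.size):
            logp += lt[:, :, self.kern._flat_idx[:, j]]
        logp += np.log(np.maximum(eta, 1e-300))[:, :, None]
        return logsumexp(logp, axis=1).sum(axis=1)


class _PoissonBridgeAdapter:
    """Same interface for the Poisson kernel, conditional on a fixed b0."""

    def __init__(self, kernel: PoissonKernel, K: int, e0: float, b0: float):
        self.kern = kernel
        self.K, self.e0, self.b0 = K, e0, b0
        self.d = 2  # features (log mu, mu)

    def posterior_blocks(self, alloc):
        counts = np.bincount(alloc, minlength=self.K).astype(float)
        ysum = np.bincount(alloc, weights=self.kern.y, minlength=self.K)
        shape = self.kern.a0 + ysum
        rate = self.b0 + counts
        return self.e0 + counts, np.column_stack([shape, rate])

    def comp_logconst(self, conc):
        shape, rate = conc[:, 0], conc[:, 1]
        return shape * np.log(rate) - gammaln(shape)

    def comp_features(self, theta):
        mu = theta[..., 0] if theta.ndim == 3 else theta
        return np.stack([np.log(np.maximum(mu, 1e-300)), mu], axis=-1)

    def comp_coef(self, conc):
        return np.column_stack([conc[:, 0] - 1.0, -conc[:, 1]])

    def sample_component(self, conc, rng):
        mu = rng.gamma(conc[:, 0], 1.0 / conc[:, 1])
        return mu[:, None]

    def log_prior_theta(self, theta):
        mu = theta[:, :, 0]
        return np.sum(self.kern.log_prior_density(mu, b0=self.b0), axis=1)

    def loglik(self, theta, eta):
        mu = theta[:, :, 0]                      # (P, K)
        y = self.kern.y
        logf = (y[None, None, :] * np.log(np.maximum(mu, 1e-300))[:, :, None]
                - mu[:, :, None] - self.kern._lgamma_y[None, None, :])
        logf += np.log(np.maximum(eta, 1e-300))[:, :, None]
        return logsumexp(logf, axis=1).sum(axis=1)


def _log_dirichlet(eta, conc):
    """(P,) log Dirichlet density; eta (P, K), conc (K,)."""
    return (gammaln(conc.sum()) - gammaln(conc).sum()
            + np.sum((conc - 1.0) * np.log(np.maximum(eta, 1e-300)), axis=-1))


def bridge_marglik(data, kernel_id: str, K: int, e0: float,
                   trace: McmcTrace, S0: int = 100,
                   rng: np.random.Generator | None = None,
                   n_importance: int | None = None,
                   max_posterior_points: int = 4000,
                   subsequence: str = "even",
                   permutation_cap: int = PERMUTATION_CAP,
                   hyper: dict | None = None) -> MarglikResult:
    """Full-permutation bridge-sampling estimate of log p(y | K), e0 fixed.

    The importance density q averages the complete-data posteriors of S0
    allocation draws from ``trace`` and is symmetrized over all K! label
    permutations; the optimal bridge between q and the unnormalized posterior
    is iterated to convergence (tolerance 1e-8), initialized from the
    importance-sampling estimate.  ``trace`` must come from a fixed-e0 SFM
    run with ``store_full_params=True``.
    """
    from .kernels import make_kernel

    rng = np.random.default_rng(rng)
    if math.factorial(K) > permutation_cap:
        raise ValueError(
            f"K! = {math.factorial(K)} exceeds the configured cap "
            f"{permutation_cap}; use a smaller K or raise the cap knowingly")
    if trace.params_full is None or trace.weights_full is None:
        raise ValueError("bridge sampling needs a trace recorded with "
                         "store_full_params=True")
    M_all = len(trace)
    if M_all < max(S0, 10):
        raise ValueError("trace too short for the requested S0")

    kernel = make_kernel(kernel_id, data, hyper or {})
    if kernel_id == "lca":
        adapter = _LcaBridgeAdapter(kernel, K, e0)
    elif kernel_id == "poisson":
        b0 = (kernel.b0_fixed if kernel.b0_fixed is not None
              else float(np.mean(trace.hyper_trace["b0"])))
        adapter = _PoissonBridgeAdapter(kernel, K, e0, b0)
    else:
        raise ValueError("bridge sampling implemented for 'lca' and 'poisson'")

    # --- importance density from S0 allocation draws ------------------------
    if subsequence == "even":
        sel = np.unique(np.linspace(0, M_all - 1, S0).astype(int))
    else:
        sel = np.sort(rng.choice(M_all, size=S0, replace=False))
    eta_conc = np.empty((sel.size, K))
    comp_conc = np.empty((sel.size, K, adapter.d if kernel_id == "lca" else 2))
    for i, m in enumerate(sel):
        eta_conc[i], comp_conc[i] = adapter.posterior_blocks(trace.alloc[m])
    coef = np.stack([adapter.comp_coef(c) for c in comp_conc])       # (S0,K,f)
    const = np.array([adapter.comp_logconst(c).sum() for c in comp_conc])
    eta_logconst = gammaln(eta_conc.sum(axis=1)) - gammaln(eta_conc).sum(axis=1)
    perms = list(itertools.permutations(range(K)))

    def log_q(theta, eta):
        """(P,) log importance density; theta (P,K,dpack), eta (P,K)."""
        feats = adapter.comp_features(theta)                       # (P,K,f)
        log_eta = np.log(np.maximum(eta, 1e-300))                  # (P,K)
        pieces = []
        for perm in perms:
            perm = list(perm)
            fp = feats[:, perm, :]
            lp = np.einsum("lkf,pkf->lp", coef, fp)
            lp += (eta_conc - 1.0) @ log_eta[:, perm].T
            lp += (const + eta_logconst)[:, None]
            pieces.append(lp)
        stacked = np.concatenate(pieces, axis=0)                   # (S0*K!, P)
        return logsumexp(stacked, axis=0) - math.log(sel.size * len(perms))

    def log_pstar(theta, eta):
        return (adapter.loglik(theta, eta)
                + adapter.log_prior_theta(theta)
                + _log_dirichlet(eta, np.full(K, e0)))

    # --- evaluation points ---------------------------------------------------
    if M_all > max_posterior_points:
        keep = np.unique(np.linspace(0, M_all - 1, max_posterior_points).astype(int))
    else:
        keep = np.arange(M_all)
    theta_p = trace.params_full[keep]
    eta_p = trace.weights_full[keep]
    L = n_importance if n_importance is not None else keep.size
    theta_q = np.empty((L, K, theta_p.shape[2]))
    eta_q = np.empty((L, K))
    which = rng.integers(0, sel.size, size=L)
    for i, l in enumerate(which):
        perm = list(perms[rng.integers(0, len(perms))])
        th = adapter.sample_component(comp_conc[l], rng)
        g = np.maximum(rng.gamma(eta_conc[l]), 1e-300)
        eta = g / g.sum()
        theta_q[i] = th[perm]
        eta_q[i] = eta[perm]

    lq_p = log_q(theta_p, eta_p)
    lp_p = log_pstar(theta_p, eta_p)
    lq_q = log_q(theta_q, eta_q)
    lp_q = log_pstar(theta_q, eta_q)

    # --- iterative optimal bridge -------------------------------------------
    Mn, Ln = keep.size, L
    log_s1 = math.log(Mn / (Mn + Ln))
    log_s2 = math.log(Ln / (Mn + Ln))
    h_q = lp_q - lq_q          # at q draws
    h_p = lp_p - lq_p          # at posterior draws
    r = logsumexp(h_q) - math.log(Ln)      # importance-sampling start
    for _ in range(1000):
        log_num = logsumexp(
            h_q - np.logaddexp(log_s1 + h_q, log_s2 + r)) - math.log(Ln)
        log_den = logsumexp(
            -np.logaddexp(log_s1 + h_p, log_s2 + r)) - math.log(Mn)
        r_new = log_num - log_den
        if abs(r_new - r) < 1e-8:
            r = r_new
            break
        r = r_new

    # --- delta-method standard error ----------------------------------------
    a = np.exp(h_q - np.logaddexp(log_s1 + h_q, log_s2 + r))
    b = np.exp(-np.logaddexp(log_s1 + h_p, log_s2 + r))
    var_log_r = (np.var(a) / (Ln * np.mean(a) ** 2)
                 + np.var(b) / (Mn * np.mean(b) ** 2))
    return MarglikResult(K=K, log_marglik=float(r), se=float(math.sqrt(var_log_r)),
                         method="bridge", S0=int(sel.size),
                         n_permutations=len(perms))
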