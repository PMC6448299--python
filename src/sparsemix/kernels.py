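"""Component distributions ("clustering kernels") for the mixture sampler.

Each kernel is bound to a dataset and supplies, for all K components at once:

* prior and complete-data posterior parameter draws (step a of the Gibbs
  sweep; empty components are refreshed from the prior, which is what makes
  the sparse prior's cluster-birth probability operative),
* the (K, N) matrix of per-observation log densities used for classification,
* updates of shared hyperparameters (the Poisson kernel's b0 level),
* the lower-dimensional functional used for relabeling in the point-process
  representation.

Conjugate kernels (categorical / latent class, Poisson) draw exactly from the
complete-data posterior.  The GLM and skew kernels perform Markov updates
that leave their full conditional invariant: adaptive random-walk Metropolis
for regression coefficients and dispersion, and the truncated-normal latent
variable augmentation for the skew-normal / skew-t family.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.special import gammaln, log_ndtr, ndtr, ndtri
from scipy.stats import norm as _norm, t as _t

__all__ = [
    "make_kernel",
    "CategoricalKernel",
    "PoissonKernel",
    "PoissonGlmKernel",
    "NegBinGlmKernel",
    "SkewNormalKernel",
    "SkewTKernel",
    "component_loglik",
    "draw_params_posterior",
    "update_shared_hyper",
    "negbin_rho_logprior",
    "negbin_rho_cdf",
    "sample_rho_prior",
    "relabel_functional",
]

RHO_C_DEFAULT = 10.0 / (1.0 + math.sqrt(2.0))  # prior median of 10


# ---------------------------------------------------------------------------
# dispersion / degrees-of-freedom prior p(rho) = 2 c rho / (rho + c)^3
# ---------------------------------------------------------------------------

def negbin_rho_logprior(rho: float | np.ndarray, c: float = RHO_C_DEFAULT):
    """Log of the normalized heavy-tailed prior 2 c rho / (rho + c)^3.

    With c = 10/(1 + sqrt 2) the prior median is 10.  Used both for the
    negative-binomial dispersion rho_k and the skew-t degrees of freedom.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0) or c <= 0:
        raise ValueError("rho and c must be positive")
    out = np.log(2.0 * c) + np.log(rho) - 3.0 * np.log(rho + c)
    return float(out) if out.ndim == 0 else out


def negbin_rho_cdf(rho, c: float = RHO_C_DEFAULT):
    """Closed-form CDF (rho / (rho + c))^2 of the dispersion prior."""
    rho = np.asarray(rho, dtype=float)
    return (rho / (rho + c)) ** 2


def sample_rho_prior(rng: np.random.Generator, c: float = RHO_C_DEFAULT,
                     size=None):
    """Exact prior draw via the inverse CDF rho = c sqrt(u) / (1 - sqrt(u))."""
    u = np.sqrt(rng.uniform(size=size))
    return c * u / (1.0 - u)


# ---------------------------------------------------------------------------
# kernel classes
# ---------------------------------------------------------------------------

class Kernel:
    """Base class; subclasses define the component distribution."""

    name: str = "abstract"

    @property
    def n_obs(self) -> int:
        raise NotImplementedError

    @property
    def param_dim(self) -> int:
        """Free dimension d of one component's parameter (uniform e0 prior)."""
        raise NotImplementedError

    def init_params(self, K: int, rng: np.random.Generator, alloc=None):
        raise NotImplementedError

    def update_params(self, params, alloc: np.ndarray, K: int,
                      rng: np.random.Generator, adapt: bool = False):
        """One sweep of step (a): posterior draw / Markov update per component."""
        raise NotImplementedError

    def grow(self, params, K_new: int, rng: np.random.Generator):
        """Append prior draws up to K_new components (DPM truncation growth)."""
        raise NotImplementedError

    def loglik_matrix(self, params) -> np.ndarray:
        """(K, N) matrix of log f(y_i | theta_k)."""
        raise NotImplementedError

    def update_hyper(self, params, rng: np.random.Generator) -> None:
        """Update shared hyperparameters in place (default: none)."""

    def functional(self, params) -> np.ndarray:
        """(K, d_f) relabeling functional phi(theta_k)."""
        raise NotImplementedError

    # serialization of per-component parameters for the trace
    def pack(self, params) -> np.ndarray:
        return self.functional(params)

    def hyper_state(self) -> dict:
        return {}


class CategoricalKernel(Kernel):
    """Latent class kernel: independent categorical variables per class.

    Data are an (N, r) array of 0-based category codes with cardinalities
    D_1..D_r; component parameters are the occurrence probabilities
    pi_{k,j,l} with conjugate symmetric Dirichlet(g0_j) priors.
    Parameters are stored as a (K, sum_j D_j) row-stochastic-by-block array.
    """

    name = "lca"

    def __init__(self, y: np.ndarray, n_categories: Sequence[int],
                 g0: float | Sequence[float] = 1.0):
        y = np.asarray(y, dtype=int)
        if y.ndim != 2:
            raise ValueError("categorical data must be 2-d (N, r)")
        self.y = y
        self.D = np.asarray(n_categories, dtype=int)
        if np.any(self.D < 2):
            raise ValueError("each variable needs >= 2 categories")
        if y.shape[1] != self.D.size:
            raise ValueError("n_categories does not match data width")
        if np.any(y < 0) or np.any(y >= self.D[None, :]):
            raise ValueError("category code out of range")
        self.g0 = np.broadcast_to(np.asarray(g0, dtype=float), self.D.shape).copy()
        if np.any(self.g0 <= 0):
            raise ValueError("g0 must be positive")
        self.offsets = np.concatenate(([0], np.cumsum(self.D)))
        # column index of each observation's category inside the packed row
        self._flat_idx = self.y + self.offsets[:-1][None, :]

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def param_dim(self) -> int:
        return int(np.sum(self.D - 1))

    def _draw_dirichlet_rows(self, conc: np.ndarray, rng) -> np.ndarray:
        """Row-wise Dirichlet draws per variable block, conc (K, sum D)."""
        g = rng.gamma(np.maximum(conc, 1e-12))
        g = np.maximum(g, 1e-300)
        for j in range(self.D.size):
            sl = slice(self.offsets[j], self.offsets[j + 1])
            g[:, sl] /= g[:, sl].sum(axis=1, keepdims=True)
        return g

    def init_params(self, K, rng, alloc=None):
        if alloc is None:
            alloc = np.zeros(self.n_obs, dtype=int)
        return self.update_params(None, alloc, K, rng)

    def update_params(self, params, alloc, K, rng, adapt=False):
        conc = np.tile(np.repeat(self.g0, self.D), (K, 1))
        # accumulate counts: for each variable, add 1 at (alloc_i, code)
        for j in range(self.D.size):
            np.add.at(conc, (alloc, self._flat_idx[:, j]), 1.0)
        return self._draw_dirichlet_rows(conc, rng)

    def grow(self, params, K_new, rng):
        K_old = params.shape[0]
        if K_new <= K_old:
            return params
        conc = np.tile(np.repeat(self.g0, self.D), (K_new - K_old, 1))
        return np.vstack([params, self._draw_dirichlet_rows(conc, rng)])

    def loglik_matrix(self, params):
        logp = np.log(params)
        out = np.zeros((params.shape[0], self.n_obs))
        for j in range(self.D.size):
            out += logp[:, self._flat_idx[:, j]]
        return out

    def functional(self, params):
        return np.asarray(params, dtype=float)

    def log_prior_density(self, params):
        """(K,) log prior density of the packed occurrence probabilities."""
        params = np.atleast_2d(params)
        out = np.zeros(params.shape[0])
        for j, D in enumerate(self.D):
            sl = slice(self.offsets[j], self.offsets[j + 1])
            a = self.g0[j]
            out += (gammaln(D * a) - D * gammaln(a)
                    + (a - 1.0) * np.log(params[:, sl]).sum(axis=1))
        return out


class PoissonKernel(Kernel):
    """Poisson kernel with hierarchical Gamma prior.

    mu_k | b0 ~ Gamma(a0, b0), b0 ~ Gamma(g0, G0) with a0 = 0.1, g0 = 0.5 and
    G0 = g0 * ybar / a0 by default; b0 may instead be fixed (``b0_fixed``).
    """

    name = "poisson"

    def __init__(self, y: np.ndarray, a0: float = 0.1, g0: float = 0.5,
                 G0: float | None = None, b0_fixed: float | None = None):
        y = np.asarray(y, dtype=float)
        if y.ndim != 1:
            raise ValueError("count data must be 1-d")
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("counts must be non-negative integers")
        self.y = y
        self.a0 = float(a0)
        self.g0 = float(g0)
        ybar = max(float(y.mean()), 1e-12)
        self.G0 = float(G0) if G0 is not None else self.g0 * ybar / self.a0
        self.b0_fixed = b0_fixed
        self.b0 = float(b0_fixed) if b0_fixed is not None else self.g0 / self.G0
        self._lgamma_y = gammaln(y + 1.0)

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def param_dim(self) -> int:
        return 1

    def init_params(self, K, rng, alloc=None):
        if alloc is None:
            alloc = np.zeros(self.n_obs, dtype=int)
        return self.update_params(None, alloc, K, rng)

    def update_params(self, params, alloc, K, rng, adapt=False):
        sums = np.bincount(alloc, weights=self.y, minlength=K)
        counts = np.bincount(alloc, minlength=K)
        return rng.gamma(self.a0 + sums, 1.0 / (self.b0 + counts))

    def grow(self, params, K_new, rng):
        K_old = params.shape[0]
        if K_new <= K_old:
            return params
        extra = rng.gamma(self.a0, 1.0 / self.b0, size=K_new - K_old)
        return np.concatenate([params, extra])

    def loglik_matrix(self, params):
        mu = np.asarray(params, dtype=float)
        return (self.y[None, :] * np.log(mu)[:, None] - mu[:, None]
                - self._lgamma_y[None, :])

    def update_hyper(self, params, rng):
        if self.b0_fixed is not None:
            return
        K = np.asarray(params).size
        self.b0 = rng.gamma(self.g0 + K * self.a0,
                            1.0 / (self.G0 + float(np.sum(params))))

    def functional(self, params):
        return np.asarray(params, dtype=float).reshape(-1, 1)

    def hyper_state(self) -> dict:
        return {"b0": self.b0}

    def log_prior_density(self, params, b0=None):
        b0 = self.b0 if b0 is None else b0
        mu = np.asarray(params, dtype=float)
        return (self.a0 * math.log(b0) - gammaln(self.a0)
                + (self.a0 - 1.0) * np.log(mu) - b0 * mu)


class _AdaptiveScale:
    """Robbins-Monro step-size adaptation toward a target acceptance rate."""

    def __init__(self, K: int, init: float = 0.5, target: float = 0.25):
        self.log_s = np.full(K, math.log(init))
        self.target = target
        self.t = 1

    def ensure(self, K: int):
        if K > self.log_s.size:
            self.log_s = np.concatenate(
                [self.log_s, np.full(K - self.log_s.size, self.log_s.mean())])

    def adapt(self, k: int, acc_prob: float):
        self.log_s[k] += (acc_prob - self.target) / self.t ** 0.6

    def tick(self):
        self.t += 1


class PoissonGlmKernel(Kernel):
    """Mixture-of-Poisson-regressions kernel, mean exp(x_i beta_k).

    beta_k ~ N(0, tau2 * I) a priori (tau2 = 4 by default).  Updated by
    component-wise adaptive random-walk Metropolis (one proposal per sweep);
    the update leaves p(beta_k | S, y) invariant.  An offset such as log
    exposure enters as a fixed column of the design matrix.
    """

    name = "poisson_glm"

    def __init__(self, y: np.ndarray, X: np.ndarray, tau2: float = 4.0):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("counts must be non-negative integers")
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("design matrix must be (N, p)")
        self.y, self.X = y, X
        self.p = X.shape[1]
        self.tau2 = float(tau2)
        self._lgamma_y = gammaln(y + 1.0)
        self._scale = _AdaptiveScale(1)

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def param_dim(self) -> int:
        return self.p

    def _logprior_beta(self, beta):
        return -0.5 * np.sum(beta ** 2, axis=-1) / self.tau2

    def _loglik_subset(self, beta, idx):
        eta = self.X[idx] @ beta
        return float(np.sum(self.y[idx] * eta - np.exp(eta) - self._lgamma_y[idx]))

    def init_params(self, K, rng, alloc=None):
        beta = rng.normal(scale=math.sqrt(self.tau2), size=(K, self.p)) * 0.1
        if alloc is not None:
            params = beta
            for _ in range(20):  # short warm start toward the posterior
                params = self.update_params(params, alloc, K, rng, adapt=True)
        return beta if alloc is None else params

    def update_params(self, params, alloc, K, rng, adapt=False):
        self._scale.ensure(K)
        beta = np.array(params, copy=True)
        if beta.shape[0] < K:
            beta = self.grow(beta, K, rng)
        counts = np.bincount(alloc, minlength=K)
        for k in range(K):
            if counts[k] == 0:
                beta[k] = rng.normal(scale=math.sqrt(self.tau2), size=self.p)
                continue
            idx = np.where(alloc == k)[0]
            s = math.exp(self._scale.log_s[k])
            prop = beta[k] + s * rng.normal(size=self.p)
            cur_lp = self._loglik_subset(beta[k], idx) + self._logprior_beta(beta[k])
            new_lp = self._loglik_subset(prop, idx) + self._logprior_beta(prop)
            acc = min(1.0, math.exp(min(0.0, new_lp - cur_lp)))
            if rng.uniform() < acc:
                beta[k] = prop
            if adapt:
                self._scale.adapt(k, acc)
        if adapt:
            self._scale.tick()
        return beta

    def grow(self, params, K_new, rng):
        K_old = params.shape[0]
        if K_new <= K_old:
            return params
        extra = rng.normal(scale=math.sqrt(self.tau2), size=(K_new - K_old, self.p))
        return np.vstack([params, extra])

    def loglik_matrix(self, params):
        eta = self.X @ np.asarray(params, dtype=float).T  # (N, K)
        ll = self.y[:, None] * eta - np.exp(eta) - self._lgamma_y[:, None]
        return ll.T

    def functional(self, params):
        return np.asarray(params, dtype=float)


class NegBinGlmKernel(PoissonGlmKernel):
    """Negative-binomial regression kernel with component dispersion rho_k.

    Mean exp(x_i beta_k), variance mean * (1 + mean / rho_k); rho_k carries
    the heavy-tailed prior 2 c rho / (rho + c)^3 with prior median 10 and is
    updated by random-walk Metropolis on log rho.
    Parameters are packed as (K, p + 1): columns [beta, rho].
    """

    name = "negbin_glm"

    def __init__(self, y, X, tau2: float = 4.0, c: float = RHO_C_DEFAULT):
        super().__init__(y, X, tau2=tau2)
        self.c = float(c)
        self._rho_scale = _AdaptiveScale(1)

    @property
    def param_dim(self) -> int:
        return self.p + 1

    def _nb_loglik_subset(self, beta, rho, idx):
        eta = self.X[idx] @ beta
        lam = np.exp(eta)
        y = self.y[idx]
        return float(np.sum(
            gammaln(y + rho) - gammaln(rho) - self._lgamma_y[idx]
            + rho * np.log(rho / (rho + lam)) + y * (eta - np.log(rho + lam))))

    def init_params(self, K, rng, alloc=None):
        beta = rng.normal(scale=math.sqrt(self.tau2), size=(K, self.p)) * 0.1
        rho = sample_rho_prior(rng, self.c, size=K)
        params = np.column_stack([beta, rho])
        if alloc is not None:
            for _ in range(20):
                params = self.update_params(params, alloc, K, rng, adapt=True)
        return params

    def update_params(self, params, alloc, K, rng, adapt=False):
        self._scale.ensure(K)
        self._rho_scale.ensure(K)
        params = np.array(params, copy=True)
        if params.shape[0] < K:
            params = self.grow(params, K, rng)
        counts = np.bincount(alloc, minlength=K)
        for k in range(K):
            beta, rho = params[k, :-1], params[k, -1]
            if counts[k] == 0:
                params[k, :-1] = rng.normal(scale=math.sqrt(self.tau2), size=self.p)
                params[k, -1] = sample_rho_prior(rng, self.c)
                continue
            idx = np.where(alloc == k)[0]
            # beta move
            s = math.exp(self._scale.log_s[k])
            prop = beta + s * rng.normal(size=self.p)
            cur = self._nb_loglik_subset(beta, rho, idx) + self._logprior_beta(beta)
            new = self._nb_loglik_subset(prop, rho, idx) + self._logprior_beta(prop)
            acc = min(1.0, math.exp(min(0.0, new - cur)))
            if rng.uniform() < acc:
                beta = prop
            if adapt:
                self._scale.adapt(k, acc)
            # rho move on the log scale (Jacobian: + log rho)
            s_r = math.exp(self._rho_scale.log_s[k])
            rho_prop = rho * math.exp(s_r * rng.normal())
            cur_lp = (self._nb_loglik_subset(beta, rho, idx)
                      + negbin_rho_logprior(rho, self.c) + math.log(rho))
            new_lp = (self._nb_loglik_subset(beta, rho_prop, idx)
                      + negbin_rho_logprior(rho_prop, self.c) + math.log(rho_prop))
            acc_r = min(1.0, math.exp(min(0.0, new_lp - cur_lp)))
            if rng.uniform() < acc_r:
                rho = rho_prop
            if adapt:
                self._rho_scale.adapt(k, acc_r)
            params[k, :-1], params[k, -1] = beta, rho
        if adapt:
            self._scale.tick()
            self._rho_scale.tick()
        return params

    def grow(self, params, K_new, rng):
        K_old = params.shape[0]
        if K_new <= K_old:
            return params
        extra_b = rng.normal(scale=math.sqrt(self.tau2), size=(K_new - K_old, self.p))
        extra_r = sample_rho_prior(rng, self.c, size=K_new - K_old)
        return np.vstack([params, np.column_stack([extra_b, extra_r])])

    def loglik_matrix(self, params):
        params = np.asarray(params, dtype=float)
        beta, rho = params[:, :-1], params[:, -1]
        eta = self.X @ beta.T                     # (N, K)
        lam = np.exp(eta)
        y = self.y[:, None]
        ll = (gammaln(y + rho[None, :]) - gammaln(rho)[None, :]
              - self._lgamma_y[:, None]
              + rho[None, :] * np.log(rho[None, :] / (rho[None, :] + lam))
              + y * (eta - np.log(rho[None, :] + lam)))
        return ll.T

    def functional(self, params):
        return np.asarray(params, dtype=float)


class SkewNormalKernel(Kernel):
    """Univariate skew-normal kernel via truncated-normal augmentation.

    The standard skew-normal pdf is 2 phi(x) Phi(alpha x); location xi_k and
    scale omega_k enter through y = xi_k + omega_k x.  Internally the kernel
    works in the (xi, psi, sigma2) parametrization

        y_i = xi + psi z_i + sigma eps_i,   z_i ~ N(0, 1) truncated to z >= 0,

    with omega^2 = sigma^2 + psi^2 and alpha = psi / sigma, which makes all
    full conditionals (z | ..., (xi, psi) | ..., sigma2 | ...) conjugate.
    Priors: xi ~ N(b_xi, B0), psi ~ N(0, B0), sigma2 ~ InvGamma(c0, C0) with
    data-driven defaults b_xi = median(y), B0 = 4 var(y), c0 = 2.5,
    C0 = (c0 - 1) var(y) / 2.
    """

    name = "skew_normal"

    def __init__(self, y: np.ndarray, b_xi: float | None = None,
                 B0: float | None = None, c0: float = 2.5,
                 C0: float | None = None):
        y = np.asarray(y, dtype=float)
        if y.ndim != 1:
            raise ValueError("continuous data must be 1-d")
        self.y = y
        v = max(float(np.var(y)), 1e-12)
        self.b_xi = float(np.median(y)) if b_xi is None else float(b_xi)
        self.B0 = 4.0 * v if B0 is None else float(B0)
        self.c0 = float(c0)
        self.C0 = (self.c0 - 1.0) * v / 2.0 if C0 is None else float(C0)

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def param_dim(self) -> int:
        return 3

    # --- internal <-> reported parametrizations ----------------------------
    @staticmethod
    def _to_natural(params):
        """(xi, psi, sigma2) -> (xi, omega, alpha)."""
        xi, psi, s2 = params[..., 0], params[..., 1], params[..., 2]
        omega = np.sqrt(s2 + psi ** 2)
        alpha = psi / np.sqrt(s2)
        return np.stack([xi, omega, alpha], axis=-1)

    def _draw_prior(self, K, rng):
        xi = rng.normal(self.b_xi, math.sqrt(self.B0), size=K)
        psi = rng.normal(0.0, math.sqrt(self.B0), size=K)
        s2 = self.C0 / rng.gamma(self.c0, size=K)
        return np.column_stack([xi, psi, s2])

    def init_params(self, K, rng, alloc=None):
        params = self._draw_prior(K, rng)
        if alloc is not None:
            for _ in range(20):
                params = self.update_params(params, alloc, K, rng)
        return params

    def _draw_z(self, y, xi, psi, s2, w, rng):
        """z_i | y_i ~ N(m, v) truncated to [0, inf); w = latent t scales.

        Inverse-CDF sampling via the survival function keeps the draw stable
        when the untruncated mean sits far below zero.
        """
        v = s2 / (w * (s2 + psi ** 2))
        m = psi * (y - xi) / (s2 + psi ** 2)
        sd = np.sqrt(v)
        a = -m / sd
        sf_a = np.maximum(ndtr(-a), 1e-300)   # P(Z > a)
        u = rng.uniform(size=np.shape(m))
        z = m - sd * ndtri(np.maximum(sf_a * (1.0 - u), 1e-300))
        return np.maximum(z, 0.0)

    def _draw_xi_psi(self, y, z, w, s2, rng):
        """(xi, psi) | z, w, s2: conjugate bivariate-normal draw from the
        weighted regression of y on (1, z), written in scalar 2x2 algebra."""
        Wd = w / s2
        A = float(np.sum(Wd)) + 1.0 / self.B0
        B = float(np.sum(Wd * z))
        C = float(np.sum(Wd * z * z)) + 1.0 / self.B0
        r1 = float(np.sum(Wd * y)) + self.b_xi / self.B0
        r2 = float(np.sum(Wd * z * y))
        det = A * C - B * B
        m1 = (C * r1 - B * r2) / det
        m2 = (A * r2 - B * r1) / det
        # Cholesky of the covariance [[C,-B],[-B,A]]/det
        c11, c12, c22 = C / det, -B / det, A / det
        l11 = math.sqrt(c11)
        l21 = c12 / l11
        l22 = math.sqrt(max(c22 - l21 * l21, 1e-300))
        e1, e2 = rng.normal(), rng.normal()
        return m1 + l11 * e1, m2 + l21 * e1 + l22 * e2

    def _update_component(self, y, w, params_k, rng):
        xi, psi, s2 = params_k
        z = self._draw_z(y, xi, psi, s2, w, rng)
        xi, psi = self._draw_xi_psi(y, z, w, s2, rng)
        resid = y - xi - psi * z
        s2 = (self.C0 + 0.5 * np.sum(w * resid ** 2)) / rng.gamma(
            self.c0 + 0.5 * y.size)
        return np.array([xi, psi, s2]), z

    def update_params(self, params, alloc, K, rng, adapt=False):
        params = np.array(params, copy=True)
        if params.shape[0] < K:
            params = self.grow(params, K, rng)
        counts = np.bincount(alloc, minlength=K)
        for k in range(K):
            if counts[k] == 0:
                params[k] = self._draw_prior(1, rng)[0]
                continue
            idx = np.where(alloc == k)[0]
            y = self.y[idx]
            params[k], _ = self._update_component(y, np.ones(y.size),
                                                  params[k], rng)
        return params

    def grow(self, params, K_new, rng):
        K_old = params.shape[0]
        if K_new <= K_old:
            return params
        return np.vstack([params, self._draw_prior(K_new - K_old, rng)])

    def loglik_matrix(self, params):
        nat = self._to_natural(np.asarray(params, dtype=float))
        xi, omega, alpha = nat[:, 0], nat[:, 1], nat[:, 2]
        z = (self.y[None, :] - xi[:, None]) / omega[:, None]
        return (math.log(2.0) - np.log(omega)[:, None]
                + _norm.logpdf(z) + log_ndtr(alpha[:, None] * z))

    def functional(self, params):
        return self._to_natural(np.asarray(params, dtype=float))


class SkewTKernel(SkewNormalKernel):
    """Univariate skew-t kernel: skew-normal scale mixture with latent
    Gamma(nu/2, nu/2) weights; nu_k is updated by MH on log nu under the
    heavy-tailed prior 2 c nu / (nu + c)^3 (prior median 10).
    Packed parameters: (xi, psi, sigma2, nu).
    """

    name = "skew_t"

    def __init__(self, y, c_nu: float = RHO_C_DEFAULT, **kwargs):
        super().__init__(y, **kwargs)
        self.c_nu = float(c_nu)
        self._nu_scale = _AdaptiveScale(1)

    @property
    def param_dim(self) -> int:
        return 4

    def _draw_prior(self, K, rng):
        base = super()._draw_prior(K, rng)
        nu = sample_rho_prior(rng, self.c_nu, size=K)
        return np.column_stack([base, nu])

    def update_params(self, params, alloc, K, rng, adapt=False):
        params = np.array(params, copy=True)
        if params.shape[0] < K:
            params = self.grow(params, K, rng)
        self._nu_scale.ensure(K)
        counts = np.bincount(alloc, minlength=K)
        for k in range(K):
            if counts[k] == 0:
                params[k] = self._draw_prior(1, rng)[0]
                continue
            idx = np.where(alloc == k)[0]
            y = self.y[idx]
            xi, psi, s2, nu = params[k]
            # latent scales W_i | y, z ... drawn jointly with z by first
            # drawing z | y, W (previous W implicit = fresh sweep): draw W
            # from its conditional given current (z implicit) via two stages
            z = self._draw_z(y, xi, psi, s2, np.ones(y.size), rng)
            resid = y - xi - psi * z
            w = rng.gamma(0.5 * nu + 1.0,
                          1.0 / (0.5 * nu + 0.5 * (resid ** 2 / s2 + z ** 2)))
            # redraw z given W, then conjugate regression updates
            z = self._draw_z(y, xi, psi, s2, w, rng)
            xi, psi = self._draw_xi_psi(y, z, w, s2, rng)
            resid = y - xi - psi * z
            s2 = (self.C0 + 0.5 * np.sum(w * resid ** 2)) / rng.gamma(
                self.c0 + 0.5 * y.size)
            # nu | W by MH on log nu
            s_nu = math.exp(self._nu_scale.log_s[k])
            nu_prop = nu * math.exp(s_nu * rng.normal())

            def _lp(v):
                return (negbin_rho_logprior(v, self.c_nu) + math.log(v)
                        + y.size * (0.5 * v * math.log(0.5 * v) - gammaln(0.5 * v))
                        + (0.5 * v - 1.0) * float(np.sum(np.log(w)))
                        - 0.5 * v * float(np.sum(w)))

            acc = min(1.0, math.exp(min(0.0, _lp(nu_prop) - _lp(nu))))
            if rng.uniform() < acc:
                nu = nu_prop
            if adapt:
                self._nu_scale.adapt(k, acc)
            params[k] = (xi, psi, s2, nu)
        if adapt:
            self._nu_scale.tick()
        return params

    def loglik_matrix(self, params):
        params = np.asarray(params, dtype=float)
        nat = self._to_natural(params[:, :3])
        xi, omega, alpha = nat[:, 0], nat[:, 1], nat[:, 2]
        nu = params[:, 3]
        z = (self.y[None, :] - xi[:, None]) / omega[:, None]
        # skew-t pdf: 2/omega t_nu(z) T_{nu+1}(alpha z sqrt((nu+1)/(nu+z^2)))
        scale_arg = alpha[:, None] * z * np.sqrt(
            (nu[:, None] + 1.0) / (nu[:, None] + z ** 2))
        return (math.log(2.0) - np.log(omega)[:, None]
                + _t.logpdf(z, nu[:, None])
                + _t.logcdf(scale_arg, nu[:, None] + 1.0))

    def functional(self, params):
        params = np.asarray(params, dtype=float)
        nat = self._to_natural(params[:, :3])
        return np.column_stack([nat, params[:, 3]])


_KERNELS = {
    "lca": CategoricalKernel,
    "poisson": PoissonKernel,
    "poisson_glm": PoissonGlmKernel,
    "negbin_glm": NegBinGlmKernel,
    "skew_normal": SkewNormalKernel,
    "skew_t": SkewTKernel,
}


def make_kernel(kernel_id: str, data, hyper: dict | None = None) -> Kernel:
    """Instantiate a kernel bound to a dataset.

    ``data`` is an (N, r) code array for "lca" (hyper must carry
    ``n_categories``), a count/continuous vector for "poisson" / skew
    kernels, or a (y, X) pair for the GLM kernels.
    """
    hyper = dict(hyper or {})
    if kernel_id not in _KERNELS:
        raise ValueError(f"unknown kernel {kernel_id!r}")
    cls = _KERNELS[kernel_id]
    if kernel_id == "lca":
        n_cat = hyper.pop("n_categories", None)
        if n_cat is None:
            n_cat = np.asarray(data, dtype=int).max(axis=0) + 1
        return cls(data, n_cat, **hyper)
    if kernel_id in ("poisson_glm", "negbin_glm"):
        y, X = data
        return cls(y, X, **hyper)
    return cls(data, **hyper)


# ---------------------------------------------------------------------------
# functional surface used by the spec-level API and the tests
# ---------------------------------------------------------------------------

def component_loglik(kernel_id: str, y, theta: dict) -> float:
    """Log density of a single observation under one component.

    ``theta`` is a plain dict: {"pi": [vecs per variable]} for "lca";
    {"mu": m} for "poisson"; {"beta": b[, "rho": r]} for the GLM kernels
    (y = (count, x_row)); {"xi", "omega", "alpha"[, "nu"]} for skew kernels.
    """
    if kernel_id == "lca":
        y = np.asarray(y, dtype=int)
        total = 0.0
        for j, p in enumerate(theta["pi"]):
            p = np.asarray(p, dtype=float)
            if y[j] < 0 or y[j] >= p.size:
                raise ValueError("category code out of range")
            total += math.log(p[y[j]])
        return total
    if kernel_id == "poisson":
        if y < 0 or y != int(y):
            raise ValueError("negative or non-integer count")
        mu = theta["mu"]
        return float(y * math.log(mu) - mu - gammaln(y + 1))
    if kernel_id in ("poisson_glm", "negbin_glm"):
        count, x = y
        if count < 0:
            raise ValueError("negative count")
        lam = math.exp(float(np.dot(x, theta["beta"])))
        if kernel_id == "poisson_glm":
            return float(count * math.log(lam) - lam - gammaln(count + 1))
        rho = theta["rho"]
        return float(gammaln(count + rho) - gammaln(rho) - gammaln(count + 1)
                     + rho * math.log(rho / (rho + lam))
                     + count * math.log(lam / (rho + lam)))
    if kernel_id in ("skew_normal", "skew_t"):
        xi, omega, alpha = theta["xi"], theta["omega"], theta["alpha"]
        if omega <= 0:
            raise ValueError("omega must be positive")
        z = (y - xi) / omega
        if kernel_id == "skew_normal":
            return float(math.log(2.0) - math.log(omega)
                         + _norm.logpdf(z) + log_ndtr(alpha * z))
        nu = theta["nu"]
        arg = alpha * z * math.sqrt((nu + 1.0) / (nu + z ** 2))
        return float(math.log(2.0) - math.log(omega)
                     + _t.logpdf(z, nu) + _t.logcdf(arg, nu + 1.0))
    raise ValueError(f"unknown kernel {kernel_id!r}")


def draw_params_posterior(kernel_id: str, data_subset, hyper: dict,
                          rng: np.random.Generator, current: dict | None = None
                          ) -> dict:
    """Draw component parameters from the complete-data posterior.

    Conjugate kernels return an exact draw (the prior if the subset is
    empty).  For the GLM and skew kernels the draw is one Markov update that
    leaves the complete-data posterior invariant, started from ``current``
    (or from a prior draw if ``current`` is None).
    """
    hyper = dict(hyper or {})
    if kernel_id == "lca":
        y = np.asarray(data_subset, dtype=int)
        n_cat = hyper["n_categories"]
        g0 = np.broadcast_to(np.asarray(hyper.get("g0", 1.0), dtype=float),
                             (len(n_cat),))
        pis = []
        for j, D in enumerate(n_cat):
            counts = (np.bincount(y[:, j], minlength=D).astype(float)
                      if y.size else np.zeros(D))
            pis.append(rng.dirichlet(g0[j] + counts))
        return {"pi": pis}
    if kernel_id == "poisson":
        y = np.asarray(data_subset, dtype=float)
        a0 = hyper.get("a0", 0.1)
        b0 = hyper["b0"]
        return {"mu": rng.gamma(a0 + y.sum(), 1.0 / (b0 + y.size))}
    if kernel_id in ("poisson_glm", "negbin_glm", "skew_normal", "skew_t"):
        # delegate to the class machinery on a single-component problem
        if kernel_id in ("poisson_glm", "negbin_glm"):
            y, X = data_subset
            kern = make_kernel(kernel_id, (np.asarray(y), np.asarray(X)), hyper)
        else:
            kern = make_kernel(kernel_id, np.asarray(data_subset, float), hyper)
        if current is None:
            params = kern.init_params(1, rng)
        else:
            params = _theta_to_row(kernel_id, current)[None, :]
        alloc = np.zeros(kern.n_obs, dtype=int)
        params = kern.update_params(params, alloc, 1, rng)
        return _row_to_theta(kernel_id, params[0], kern)
    raise ValueError(f"unknown kernel {kernel_id!r}")


def _theta_to_row(kernel_id, theta):
    if kernel_id == "poisson_glm":
        return np.asarray(theta["beta"], dtype=float)
    if kernel_id == "negbin_glm":
        return np.concatenate([theta["beta"], [theta["rho"]]])
    # skew kernels: convert reported (xi, omega, alpha) to internal (xi, psi, s2)
    xi, omega, alpha = theta["xi"], theta["omega"], theta["alpha"]
    delta = alpha / math.sqrt(1.0 + alpha ** 2)
    psi = omega * delta
    s2 = omega ** 2 - psi ** 2
    row = [xi, psi, s2]
    if kernel_id == "skew_t":
        row.append(theta["nu"])
    return np.asarray(row, dtype=float)


def _row_to_theta(kernel_id, row, kern):
    if kernel_id == "poisson_glm":
        return {"beta": row.copy()}
    if kernel_id == "negbin_glm":
        return {"beta": row[:-1].copy(), "rho": float(row[-1])}
    nat = SkewNormalKernel._to_natural(row[:3])
    theta = {"xi": float(nat[0]), "omega": float(nat[1]), "alpha": float(nat[2])}
    if kernel_id == "skew_t":
        theta["nu"] = float(row[3])
    return theta


def update_shared_hyper(kernel_id: str, component_params, hyper: dict,
                        rng: np.random.Generator) -> dict:
    """Update shared hyperparameters; only the Poisson kernel has one (b0)."""
    hyper = dict(hyper)
    if kernel_id != "poisson":
        return hyper
    mu = np.asarray(component_params, dtype=float)
    a0 = hyper.get("a0", 0.1)
    g0 = hyper.get("g0", 0.5)
    G0 = hyper["G0"]
    hyper["b0"] = rng.gamma(g0 + mu.size * a0, 1.0 / (G0 + mu.sum()))
    return hyper


def relabel_functional(kernel_id: str, theta: dict) -> np.ndarray:
    """Lower-dimensional functional phi(theta_k) used for relabeling."""
    if kernel_id == "lca":
        return np.concatenate([np.asarray(p, dtype=float) for p in theta["pi"]])
    if kernel_id == "poisson":
        return np.asarray([theta["mu"]], dtype=float)
    if kernel_id in ("poisson_glm", "negbin_glm"):
        return np.asarray(theta["beta"], dtype=float)
    if kernel_id in ("skew_normal", "skew_t"):
        return np.asarray([theta["xi"], theta["omega"], theta["alpha"]],
                          dtype=float)
    raise ValueError(f"unknown kernel {kernel_id!r}")
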