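"""Unified stick-breaking Gibbs sampler for sparse finite mixtures (SFM) and
Dirichlet process mixtures (DPM).

One sweep consists of

(a) component parameters: complete-data posterior draws for occupied
    components, prior draws for empty ones (the empty-component refresh is
    what makes the sparse prior's cluster-birth probability operative);
(b) sticks from their Beta full conditionals, weights by stick-breaking;
(c) classification: standard multinomial draws for the SFM; for the DPM,
    slice sampling with deterministic slice bounds xi_k = (1-kappa) kappa^(k-1)
    (kappa = 0.8) and adaptive truncation;
(d) a random-walk Metropolis-Hastings step for the precision parameter
    (e0 or alpha) targeting its partition-conditional posterior, with
    Robbins-Monro step adaptation during burn-in.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .kernels import Kernel, make_kernel
from .priors_weights import (PriorConfig, StickSet, sample_sticks_conditional,
                             stick_breaking_weights)

__all__ = [
    "MixtureState",
    "McmcTrace",
    "run_mcmc",
    "classify_slice",
    "log_partition_prob_sfm",
    "log_partition_prob_dpm",
    "update_precision",
    "PrecisionSampler",
    "KAPPA",
]

KAPPA = 0.8          # slice-bound decay for the DPM sampler
_MAX_TRUNCATION = 512


# ---------------------------------------------------------------------------
# partition probabilities (step d targets)
# ---------------------------------------------------------------------------

def _lgamma_stable(x):
    """log Gamma(x) for x > 0, written as log Gamma(1+x) - log x for small x
    to avoid overflow of Gamma itself in downstream ratios."""
    x = np.asarray(x, dtype=float)
    small = x < 0.1
    out = np.where(small, gammaln(1.0 + x) - np.log(np.where(small, x, 1.0)),
                   gammaln(np.where(small, 1.0, x)))
    return out


def log_partition_prob_sfm(counts, e0: float, K: int | None = None) -> float:
    """log p(P | e0, K) for a labeled-component finite mixture partition:

        K!/(K-K+)! * Gamma(K e0)/Gamma(N + K e0)
                   * prod_{k: N_k>0} Gamma(N_k + e0)/Gamma(e0),

    stable down to e0 ~ 1e-12 via Gamma(x) = Gamma(1+x)/x for small x.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if e0 <= 0:
        raise ValueError("e0 must be positive")
    K = counts.size if K is None else int(K)
    N = counts.sum()
    if N < 1:
        raise ValueError("need at least one observation")
    occ = counts[counts > 0]
    kplus = occ.size
    return float(
        gammaln(K + 1) - gammaln(K - kplus + 1)
        + _lgamma_stable(K * e0) - gammaln(N + K * e0)
        + np.sum(_lgamma_stable(occ + e0)) - kplus * _lgamma_stable(e0))


def log_partition_prob_dpm(counts, alpha: float) -> float:
    """log p(P | alpha) = log[alpha^K+ Gamma(alpha)/Gamma(N+alpha)
    prod_{k:N_k>0} Gamma(N_k)] for a Dirichlet-process partition."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    N = counts.sum()
    occ = counts[counts > 0]
    kplus = occ.size
    return float(kplus * math.log(alpha)
                 + _lgamma_stable(alpha) - gammaln(N + alpha)
                 + np.sum(gammaln(occ)))


# ---------------------------------------------------------------------------
# precision parameter (step d)
# ---------------------------------------------------------------------------

class PrecisionSampler:
    """Random-walk MH on the log precision with Robbins-Monro adaptation.

    Targets p(precision | P) ∝ p(P | precision) p(precision); adaptation
    (toward ~0.4 acceptance) runs during burn-in only, preserving ergodicity
    of the post-burn-in chain.
    """

    def __init__(self, prior: PriorConfig, d: int | None = None,
                 init_step: float = 0.5, target: float = 0.4):
        self.prior = prior
        self.log_step = math.log(init_step)
        self.target = target
        self.t = 1
        self.upper = None
        if prior.precision_prior == "uniform":
            self.upper = prior.upper if prior.upper is not None else d / 2.0
            if self.upper is None or self.upper <= 0:
                raise ValueError("uniform prior needs a positive upper bound")

    def _log_prior(self, x: float) -> float:
        p = self.prior
        if p.precision_prior == "gamma":
            return (p.shape - 1.0) * math.log(x) - p.rate * x
        if p.precision_prior == "uniform":
            return 0.0 if 0.0 < x < self.upper else -math.inf
        raise AssertionError("fixed prior has no MH step")

    def _log_target(self, x: float, counts, K: int) -> float:
        lp = self._log_prior(x)
        if not math.isfinite(lp):
            return -math.inf
        if self.prior.family == "sparse_finite":
            return lp + log_partition_prob_sfm(counts, x, K)
        return lp + log_partition_prob_dpm(counts, x)

    def step(self, counts, K: int, current: float,
             rng: np.random.Generator, adapt: bool = False) -> float:
        if self.prior.precision_prior == "fixed":
            return current
        step = math.exp(self.log_step)
        prop = current * math.exp(step * rng.normal())
        # log-scale random walk: Jacobian contributes log(prop/current)
        num = self._log_target(prop, counts, K) + math.log(prop)
        den = self._log_target(current, counts, K) + math.log(current)
        acc = 0.0 if num == -math.inf else min(1.0, math.exp(min(0.0, num - den)))
        new = prop if rng.uniform() < acc else current
        if adapt:
            self.log_step += (acc - self.target) / self.t ** 0.6
            self.t += 1
        return new


def update_precision(counts, K: int, family: str, prior: PriorConfig,
                     current: float, rng: np.random.Generator,
                     step_state: PrecisionSampler | None = None,
                     adapt: bool = False, d: int | None = None) -> float:
    """One MH update of e0 (SFM) or alpha (DPM) given the partition."""
    if step_state is None:
        step_state = PrecisionSampler(prior, d=d)
    return step_state.step(counts, K, current, rng, adapt=adapt)


# ---------------------------------------------------------------------------
# state, classification
# ---------------------------------------------------------------------------

@dataclass
class MixtureState:
    """Current sampler state; counts are kept consistent with allocations."""

    params: np.ndarray
    sticks: StickSet
    weights: np.ndarray
    alloc: np.ndarray
    counts: np.ndarray
    precision: float
    slice_u: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.weights.size

    @property
    def kplus(self) -> int:
        return int(np.sum(self.counts > 0))


def _slice_kmax(u: np.ndarray, kappa: float = KAPPA) -> np.ndarray:
    """Largest component index k with xi_k > u for xi_k = (1-kappa) kappa^(k-1)."""
    t = np.log(u / (1.0 - kappa)) / math.log(kappa)
    return 1 + np.floor(t).astype(int)


def _categorical_rows(logp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one index per column of a (K, N) log-probability matrix
    (unnormalized) via the Gumbel-max trick."""
    finite = np.max(logp, axis=0)
    if np.any(~np.isfinite(finite)):
        bad = int(np.argmin(np.isfinite(finite)))
        raise FloatingPointError(
            f"all component likelihoods vanished for observation {bad}")
    g = rng.gumbel(size=logp.shape)
    return np.argmax(logp + g, axis=0)


def classify_slice(state: MixtureState, kernel: Kernel, family: str,
                   prior: PriorConfig, rng: np.random.Generator,
                   kappa: float = KAPPA) -> MixtureState:
    """Step (c): update allocations (and, for the DPM, slice variables and
    the truncation level).

    SFM: xi_k = 1, S_i ~ Categorical(eta_k f(y_i | theta_k)).
    DPM: u_i ~ U[0, xi_{S_i}]; the truncation is grown with prior stick/
    parameter draws until it covers every admissible component
    (k <= k_max(u_i) for all i) and the leftover mass satisfies
    1 - sum_k eta_k < min_i u_i; then
    S_i ~ Categorical(I{u_i < xi_k} eta_k f(y_i | theta_k) / xi_k).
    """
    if family == "sparse_finite":
        with np.errstate(divide="ignore"):
            logp = (np.log(state.weights)[:, None]
                    + kernel.loglik_matrix(state.params))
        alloc = _categorical_rows(logp, rng)
        counts = np.bincount(alloc, minlength=state.K)
        return MixtureState(state.params, state.sticks, state.weights,
                            alloc, counts, state.precision, None)

    # --- DPM ---------------------------------------------------------------
    xi_of = lambda k: (1.0 - kappa) * kappa ** (np.asarray(k, dtype=float) - 1.0)
    u = rng.uniform(0.0, xi_of(state.alloc + 1))
    u = np.maximum(u, 1e-300)
    needed = int(np.max(_slice_kmax(u, kappa)))
    sticks = state.sticks.sticks
    params = state.params
    # grow truncation: new sticks are prior Beta(1, alpha) draws (their
    # occupation counts are zero), new parameters are prior draws
    while sticks.size < needed or (
            float(np.prod(1.0 - sticks)) >= float(np.min(u))):
        add = max(8, sticks.size // 2)
        new_v = rng.beta(1.0, state.precision, size=add)
        sticks = np.concatenate([sticks, np.clip(new_v, 1e-300, 1.0 - 1e-16)])
        if sticks.size > _MAX_TRUNCATION:
            # remainder decays geometrically; at this depth xi_k and the
            # remaining mass are both far below min(u) in double precision
            break
        params = kernel.grow(params, sticks.size, rng)
    params = kernel.grow(params, sticks.size, rng)
    K = sticks.size
    weights = stick_breaking_weights(sticks)
    ks = np.arange(1, K + 1)
    log_xi = math.log(1.0 - kappa) + (ks - 1.0) * math.log(kappa)
    with np.errstate(divide="ignore"):
        logp = (np.log(weights) - log_xi)[:, None] + kernel.loglik_matrix(params)
        admissible = log_xi[:, None] > np.log(u)[None, :]
    logp = np.where(admissible, logp, -np.inf)
    alloc = _categorical_rows(logp, rng)
    counts = np.bincount(alloc, minlength=K)
    return MixtureState(params, StickSet(sticks), weights, alloc, counts,
                        state.precision, u)


# ---------------------------------------------------------------------------
# trace
# ---------------------------------------------------------------------------

@dataclass
class McmcTrace:
    """Per-iteration records of the retained Gibbs draws.

    Occupied-component records are ragged (K+ varies); they are stored as
    lists keyed by iteration.  Full parameter/weight storage (needed by
    bridge sampling) is only available for fixed-K SFM runs.
    """

    kplus: np.ndarray
    precision: np.ndarray
    alloc: np.ndarray
    occ_index: list
    occ_weights: list
    occ_functional: list
    weights_full: np.ndarray | None = None
    params_full: np.ndarray | None = None
    hyper_trace: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.kplus.size

    # --- serialization: columnar npz + JSON sidecar ------------------------
    def save(self, path: str) -> None:
        path = str(path)
        offsets = np.cumsum([0] + [a.size for a in self.occ_index])
        func_dim = self.occ_functional[0].shape[1] if self.occ_functional else 0
        payload = {
            "kplus": self.kplus, "precision": self.precision,
            "alloc": self.alloc,
            "occ_index_flat": np.concatenate(self.occ_index) if self.occ_index else np.zeros(0, int),
            "occ_weights_flat": np.concatenate(self.occ_weights) if self.occ_weights else np.zeros(0),
            "occ_functional_flat": (np.vstack(self.occ_functional)
                                    if self.occ_functional else np.zeros((0, 0))),
            "offsets": offsets,
        }
        if self.weights_full is not None:
            payload["weights_full"] = self.weights_full
        if self.params_full is not None:
            payload["params_full"] = self.params_full
        for key, arr in self.hyper_trace.items():
            payload[f"hyper_{key}"] = arr
        np.savez(path if path.endswith(".npz") else path + ".npz", **payload)
        side = dict(self.meta)
        side["hyper_keys"] = list(self.hyper_trace.keys())
        side["func_dim"] = func_dim
        with open((path[:-4] if path.endswith(".npz") else path) + ".json",
                  "w") as fh:
            json.dump(side, fh, indent=1, default=str)

    @classmethod
    def load(cls, path: str) -> "McmcTrace":
        path = str(path)
        base = path[:-4] if path.endswith(".npz") else path
        data = np.load(base + ".npz")
        with open(base + ".json") as fh:
            meta = json.load(fh)
        offsets = data["offsets"]
        occ_index, occ_weights, occ_functional = [], [], []
        flat_i, flat_w = data["occ_index_flat"], data["occ_weights_flat"]
        flat_f = data["occ_functional_flat"]
        for m in range(offsets.size - 1):
            sl = slice(offsets[m], offsets[m + 1])
            occ_index.append(flat_i[sl])
            occ_weights.append(flat_w[sl])
            occ_functional.append(flat_f[sl])
        hyper = {k: data[f"hyper_{k}"] for k in meta.pop("hyper_keys", [])}
        meta.pop("func_dim", None)
        return cls(kplus=data["kplus"], precision=data["precision"],
                   alloc=data["alloc"], occ_index=occ_index,
                   occ_weights=occ_weights, occ_functional=occ_functional,
                   weights_full=(data["weights_full"]
                                 if "weights_full" in data.files else None),
                   params_full=(data["params_full"]
                                if "params_full" in data.files else None),
                   hyper_trace=hyper, meta=meta)


# ---------------------------------------------------------------------------
# initial classification
# ---------------------------------------------------------------------------

def _init_features(kernel: Kernel) -> np.ndarray:
    """Feature matrix for the k-means starting classification: one-hot
    dummies for categorical data, standardized responses otherwise."""
    from .kernels import CategoricalKernel

    if isinstance(kernel, CategoricalKernel):
        N = kernel.n_obs
        out = np.zeros((N, int(kernel.D.sum())))
        out[np.arange(N)[:, None], kernel._flat_idx] = 1.0
        return out
    y = np.asarray(kernel.y, dtype=float).reshape(-1, 1)
    sd = y.std()
    return (y - y.mean()) / (sd if sd > 0 else 1.0)


def _init_alloc(kernel: Kernel, K: int, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    X = _init_features(kernel)
    k_eff = min(K, np.unique(X, axis=0).shape[0])
    km = KMeans(n_clusters=k_eff, n_init=10, random_state=seed % (2 ** 31))
    return km.fit_predict(X).astype(int)


# ---------------------------------------------------------------------------
# main driver
# ---------------------------------------------------------------------------

def run_mcmc(data, kernel, prior: PriorConfig, n_burnin: int = 8000,
             n_iter: int = 8000, seed: int | None = None, thin: int = 1,
             store_full_params: bool = False, kappa: float = KAPPA,
             init: str = "kmeans") -> McmcTrace:
    """Run the unified Gibbs sampler and return the retained trace.

    ``kernel`` is a kernel id string (a kernel instance bound to ``data``
    is built from ``prior.kernel_hyper``) or an already-bound Kernel.
    ``store_full_params`` additionally records every component's packed
    parameters and the full weight vector per iteration (fixed-K SFM only;
    required by bridge-sampling marginal likelihoods).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    if not isinstance(kernel, Kernel):
        kernel = make_kernel(kernel, data, prior.kernel_hyper)
    N = kernel.n_obs
    if N == 0:
        raise ValueError("data is empty")
    family = prior.family
    if store_full_params and family != "sparse_finite":
        raise ValueError("full parameter storage requires a fixed-K SFM run")

    K0 = min(prior.K, N)
    if init == "kmeans":
        alloc = _init_alloc(kernel, K0, seed if seed is not None else 0)
    else:
        alloc = rng.integers(0, K0, size=N)
    K = prior.K if family == "sparse_finite" else max(prior.K, K0)
    counts = np.bincount(alloc, minlength=K)

    precision = prior.initial_precision()
    prec_sampler = PrecisionSampler(prior, d=kernel.param_dim)
    params = kernel.init_params(K, rng, alloc=alloc)
    sticks = sample_sticks_conditional(counts, prior, precision, rng)
    state = MixtureState(params, sticks, sticks.weights, alloc, counts,
                         precision, None)

    M = n_iter // thin
    kplus_tr = np.empty(M, dtype=int)
    prec_tr = np.empty(M)
    alloc_tr = np.empty((M, N), dtype=np.int32)
    occ_index, occ_weights, occ_func = [], [], []
    weights_full = np.empty((M, K)) if store_full_params else None
    params_full = None
    hyper_tr = {k: np.empty(M) for k in kernel.hyper_state()}

    stored = 0
    total = n_burnin + n_iter
    for it in range(total):
        burnin = it < n_burnin
        # (a) component parameters (occupied: posterior, empty: prior)
        state.params = kernel.update_params(state.params, state.alloc,
                                            state.K, rng, adapt=burnin)
        kernel.update_hyper(state.params, rng)
        # (b) sticks and weights
        state.sticks = sample_sticks_conditional(state.counts, prior,
                                                 state.precision, rng)
        state.weights = state.sticks.weights
        # (c) classification
        state = classify_slice(state, kernel, family, prior, rng, kappa=kappa)
        # (d) precision parameter
        state.precision = prec_sampler.step(state.counts, state.K,
                                            state.precision, rng, adapt=burnin)
        # keep the DPM truncation from creeping upward: sticks/params of the
        # unoccupied tail are regenerated from the prior next sweep anyway
        if family != "sparse_finite":
            keep = max(int(state.alloc.max()) + 1, K0)
            if keep < state.K:
                state = MixtureState(
                    state.params[:keep], StickSet(state.sticks.sticks[:keep]),
                    state.weights[:keep], state.alloc, state.counts[:keep],
                    state.precision, state.slice_u)
        if burnin or (it - n_burnin) % thin:
            continue
        occ = np.where(state.counts > 0)[0]
        kplus_tr[stored] = occ.size
        prec_tr[stored] = state.precision
        alloc_tr[stored] = state.alloc
        occ_index.append(occ.copy())
        occ_weights.append(state.weights[occ].copy())
        occ_func.append(kernel.functional(state.params)[occ].copy())
        if store_full_params:
            weights_full[stored] = state.weights
            packed = kernel.pack(state.params)
            if params_full is None:
                params_full = np.empty((M,) + packed.shape)
            params_full[stored] = packed
        for key, val in kernel.hyper_state().items():
            hyper_tr[key][stored] = val
        stored += 1

    meta = {"family": family, "K": int(prior.K), "N": int(N),
            "kernel": kernel.name, "n_burnin": int(n_burnin),
            "n_iter": int(n_iter), "thin": int(thin), "seed": seed,
            "kappa": kappa, "precision_prior": prior.precision_prior}
    return McmcTrace(kplus=kplus_tr[:stored], precision=prec_tr[:stored],
                     alloc=alloc_tr[:stored], occ_index=occ_index,
                     occ_weights=occ_weights, occ_functional=occ_func,
                     weights_full=weights_full, params_full=params_full,
                     hyper_trace={k: v[:stored] for k, v in hyper_tr.items()},
                     meta=meta)
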