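"""Weight-distribution machinery shared by sparse finite mixtures (SFM) and
Dirichlet process mixtures (DPM).

Both model families draw their mixture weights from a stick-breaking
construction eta_k = v_k * prod_{j<k} (1 - v_j).  They differ only in the
Beta prior on the sticks:

* SFM with symmetric Dirichlet(e0) weight prior:
  v_k ~ Beta(e0, (K - k) e0) for k < K and v_K = 1, which is exactly the
  stick representation of a Dirichlet_K(e0) vector.
* DPM with concentration alpha: v_k ~ Beta(1, alpha), k = 1, 2, ...

The module is stateless: it produces sticks/weights for a requested length;
truncation bookkeeping for the DPM lives in the sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "PriorConfig",
    "StickSet",
    "stick_breaking_weights",
    "sample_sticks_conditional",
    "match_priors",
    "prior_kplus_pmf",
]

Family = Literal["sparse_finite", "dirichlet_process"]


@dataclass
class PriorConfig:
    """Model family and prior on the precision parameter (e0 or alpha).

    Parameters
    ----------
    family : {"sparse_finite", "dirichlet_process"}
    K : int
        Number of components (SFM) or initial truncation level (DPM).
    precision_prior : {"fixed", "gamma", "uniform"}
        Prior on e0 (SFM) / alpha (DPM).  ``uniform`` is the U[0, d/2] prior
        derived from the overfitting-mixture asymptotics (d = dimension of a
        component parameter, supplied by the kernel); it is only meaningful
        for sparse finite mixtures.
    value : float
        Fixed value of the precision parameter (``fixed`` prior) or its
        initial value otherwise.
    shape, rate : float
        Gamma prior hyperparameters (``gamma`` prior).
    upper : float or None
        Upper bound of the uniform prior; if None the sampler fills in d/2.
    kernel_hyper : dict
        Kernel-specific hyperparameters, passed through to the kernel.
    """

    family: Family = "sparse_finite"
    K: int = 10
    precision_prior: Literal["fixed", "gamma", "uniform"] = "gamma"
    value: float | None = None
    shape: float = 1.0
    rate: float = 200.0
    upper: float | None = None
    kernel_hyper: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("sparse_finite", "dirichlet_process"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.precision_prior == "fixed":
            if self.value is None or self.value <= 0:
                raise ValueError("fixed precision prior needs value > 0")
        elif self.precision_prior == "gamma":
            if self.shape <= 0 or self.rate <= 0:
                raise ValueError("gamma prior needs shape > 0 and rate > 0")
        elif self.precision_prior == "uniform":
            if self.family != "sparse_finite":
                raise ValueError("uniform precision prior is only supported "
                                 "for family='sparse_finite'")
            if self.upper is not None and self.upper <= 0:
                raise ValueError("uniform prior upper bound must be > 0")
        else:
            raise ValueError(f"unknown precision prior {self.precision_prior!r}")

    def initial_precision(self) -> float:
        if self.precision_prior == "fixed":
            return float(self.value)
        if self.value is not None:
            return float(self.value)
        if self.precision_prior == "gamma":
            return self.shape / self.rate
        return (self.upper or 1.0) / 2.0


@dataclass
class StickSet:
    """Sticks v_1..v_K together with the implied weights."""

    sticks: np.ndarray

    def __post_init__(self) -> None:
        self.sticks = np.asarray(self.sticks, dtype=float)
        if self.sticks.ndim != 1 or self.sticks.size < 1:
            raise ValueError("sticks must be a non-empty 1-d array")
        if np.any(self.sticks <= 0.0) or np.any(self.sticks > 1.0):
            raise ValueError("sticks must lie in (0, 1]")

    @property
    def weights(self) -> np.ndarray:
        return stick_breaking_weights(self)


def stick_breaking_weights(sticks: StickSet | np.ndarray) -> np.ndarray:
    """Map sticks to mixture weights: eta_k = v_k * prod_{j<k} (1 - v_j).

    If the last stick equals 1 (SFM convention) the weights sum to 1 exactly.
    """
    v = sticks.sticks if isinstance(sticks, StickSet) else np.asarray(sticks, dtype=float)
    if np.any(v <= 0.0) or np.any(v > 1.0):
        raise ValueError("sticks must lie in (0, 1]")
    # cumulative product of leftover mass, shifted by one
    leftover = np.concatenate(([1.0], np.cumprod(1.0 - v[:-1])))
    return v * leftover


def sample_sticks_conditional(
    counts: np.ndarray,
    prior: PriorConfig,
    precision: float,
    rng: np.random.Generator,
) -> StickSet:
    """Draw the sticks from their full conditional given occupation counts.

    v_k | S ~ Beta(a_k + N_k, b_k + sum_{l>k} N_l) with (a_k, b_k) = (e0,
    (K-k) e0) for the SFM (and v_K = 1) and (1, alpha) for the DPM.  The
    length of the returned stick set equals len(counts).
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("occupation counts must be non-negative")
    K = counts.size
    tail = np.concatenate((np.cumsum(counts[::-1])[::-1][1:], [0.0]))
    if prior.family == "sparse_finite":
        a = precision + counts
        b = precision * (K - 1 - np.arange(K)) + tail
        v = np.empty(K)
        if K > 1:
            v[:-1] = rng.beta(a[:-1], b[:-1])
        v[-1] = 1.0
    else:
        a = 1.0 + counts
        b = precision + tail
        v = rng.beta(a, b)
    # guard against degenerate 0/1 draws from beta at extreme shapes
    v = np.clip(v, 1e-300, 1.0)
    if prior.family == "sparse_finite":
        v[-1] = 1.0
    return StickSet(v)


def match_priors(
    direction: Literal["dpm_to_sfm", "sfm_to_dpm"],
    shape: float,
    rate: float,
    K: int,
) -> tuple[float, float]:
    """Translate a Gamma prior between the DPM and SFM parametrizations.

    The asymptotic relation e0 ~ alpha/K maps alpha ~ Gamma(a, b) to
    e0 ~ Gamma(a, K b) and back; the round trip is the identity.
    """
    if shape <= 0 or rate <= 0:
        raise ValueError("shape and rate must be > 0")
    if K < 1:
        raise ValueError("K must be >= 1")
    if direction == "dpm_to_sfm":
        return shape, rate * K
    if direction == "sfm_to_dpm":
        return shape, rate / K
    raise ValueError(f"unknown direction {direction!r}")


def prior_kplus_pmf(
    N: int,
    K: int,
    e0: float,
    n_draws: int = 10000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Monte-Carlo estimate of the prior pmf of the number of data clusters.

    Simulates eta ~ Dirichlet_K(e0), occupation counts ~ Multinomial(N, eta)
    and counts the non-empty components K+.  Returns a vector of length K
    with entry k-1 = P(K+ = k).
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    if N < 1 or K < 1 or e0 <= 0:
        raise ValueError("require N >= 1, K >= 1, e0 > 0")
    rng = np.random.default_rng(rng)
    if K == 1:
        out = np.zeros(1)
        out[0] = 1.0
        return out
    # gamma representation of the Dirichlet keeps this vectorized
    g = rng.gamma(e0, size=(n_draws, K))
    eta = g / g.sum(axis=1, keepdims=True)
    kplus = np.empty(n_draws, dtype=int)
    for m in range(n_draws):
        counts = rng.multinomial(N, eta[m])
        kplus[m] = K - int(np.sum(counts == 0))
    pmf = np.bincount(kplus, minlength=K + 1)[1:].astype(float)
    return pmf / n_draws


def exact_prior_kplus_pmf(N: int, K: int, e0: float) -> np.ndarray:
    """Exact prior pmf of K+ by Dirichlet-multinomial enumeration (tiny N, K).

    Test oracle: enumerates all compositions of N into K labeled parts and
    accumulates the Dirichlet-multinomial probability by number of non-empty
    parts.  Exponential in K; intended for N <= ~8, K <= ~4.
    """
    from itertools import product
    from scipy.special import gammaln

    pmf = np.zeros(K)
    base = (gammaln(K * e0) - gammaln(N + K * e0)
            + gammaln(N + 1) - K * gammaln(e0))
    for counts in product(range(N + 1), repeat=K):
        if sum(counts) != N:
            continue
        n = np.array(counts, dtype=float)
        logp = base + np.sum(gammaln(n + e0)) - np.sum(gammaln(n + 1))
        kplus = int(np.sum(n > 0))
        pmf[kplus - 1] += math.exp(logp)
    return pmf
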