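"""Posterior summaries of the number of clusters, label-switching resolution
in the point-process representation, MAP partition and clustering metrics.

The relabeling procedure pools the occupied-component functionals of all
draws with K+ equal to the estimated number of clusters, clusters them with
k-means into K-hat groups, and keeps only draws whose occupied components map
one-to-one onto the k-means centers; non-bijective draws are discarded and
their fraction reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sampler import McmcTrace

__all__ = [
    "ClusterSolution",
    "count_clusters",
    "kplus_posterior",
    "relabel_draws",
    "map_partition",
    "adjusted_rand_index",
    "error_rate",
    "hpd_interval",
    "identify",
]


def count_clusters(counts) -> int:
    """Number of non-empty components: K - #{k : N_k = 0}."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return int(np.sum(counts > 0))


def kplus_posterior(trace: McmcTrace):
    """Empirical posterior pmf of K+ and its mode (ties -> smaller K+).

    Returns (pmf, mode) where pmf[k] = Pr(K+ = k | y) as a dict.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    values, freq = np.unique(trace.kplus, return_counts=True)
    pmf = {int(k): f / len(trace) for k, f in zip(values, freq)}
    mode = int(values[np.argmax(freq)])  # np.unique sorts: ties -> smaller
    return pmf, mode


@dataclass
class RelabeledDraws:
    """Draws with K+ = K-hat after k-means relabeling."""

    khat: int
    functionals: np.ndarray      # (n_kept, khat, d)
    weights: np.ndarray          # (n_kept, khat), renormalized over K-hat
    allocations: np.ndarray      # (n_kept, N) relabeled to 0..khat-1
    discard_fraction: float
    kept_index: np.ndarray       # indices into the K+ = khat subset


def relabel_draws(trace: McmcTrace, khat: int, seed: int | None = None
                  ) -> RelabeledDraws:
    """Resolve label switching by k-means in the point-process representation.

    Only draws with exactly ``khat`` occupied components are used.  The
    occupied-component functionals of those draws are pooled and clustered
    into ``khat`` centers (k-means++, 10 restarts); a draw is kept iff its
    occupied components receive ``khat`` distinct labels.  Occupied-component
    weights are renormalized to sum to one within each kept draw.
    """
    from sklearn.cluster import KMeans

    if khat < 1:
        raise ValueError("khat must be >= 1")
    sel = np.where(trace.kplus == khat)[0]
    if sel.size == 0:
        raise ValueError(
            f"no draws with K+ = {khat}; choose a different khat "
            f"(posterior support: {sorted(set(trace.kplus.tolist()))})")
    funcs = [trace.occ_functional[m] for m in sel]
    pooled = np.vstack(funcs)
    if khat == 1:
        labels = np.zeros(pooled.shape[0], dtype=int)
    else:
        km = KMeans(n_clusters=khat, n_init=10, init="k-means++",
                    random_state=(seed or 0) % (2 ** 31))
        labels = km.fit_predict(pooled)
    labels_per_draw = np.split(labels, np.cumsum([f.shape[0] for f in funcs])[:-1])

    kept, out_f, out_w, out_a = [], [], [], []
    N = trace.alloc.shape[1]
    for pos, m in enumerate(sel):
        lab = labels_per_draw[pos]
        if np.unique(lab).size != khat:
            continue
        kept.append(pos)
        order = np.empty(khat, dtype=int)
        order[lab] = np.arange(khat)          # occupied slot for each label
        out_f.append(trace.occ_functional[m][order])
        w = trace.occ_weights[m][order]
        out_w.append(w / w.sum())
        # map raw component indices -> new labels
        comp_to_label = {int(c): int(l)
                         for c, l in zip(trace.occ_index[m], lab)}
        out_a.append(np.fromiter((comp_to_label[int(s)] for s in trace.alloc[m]),
                                 dtype=int, count=N))
    if not kept:
        raise ValueError("k-means relabeling produced no bijective draws")
    return RelabeledDraws(
        khat=khat,
        functionals=np.stack(out_f),
        weights=np.stack(out_w),
        allocations=np.stack(out_a),
        discard_fraction=1.0 - len(kept) / sel.size,
        kept_index=np.asarray(kept, dtype=int),
    )


def map_partition(relabeled: RelabeledDraws | np.ndarray) -> np.ndarray:
    """MAP partition: per observation the most frequent relabeled allocation
    (ties broken toward the lowest label)."""
    alloc = (relabeled.allocations if isinstance(relabeled, RelabeledDraws)
             else np.asarray(relabeled))
    n_lab = int(alloc.max()) + 1
    counts = np.stack([np.sum(alloc == lab, axis=0) for lab in range(n_lab)])
    return np.argmax(counts, axis=0)  # argmax takes the lowest index on ties


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    m = max(1, int(np.ceil(prob * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


@dataclass
class ClusterSolution:
    """Identified cluster solution: K-hat, per-cluster posterior means and
    95% HPD intervals of the relabel functional and the weights, the MAP
    partition, and the fraction of draws discarded as non-permutations."""

    khat: int
    functional_mean: np.ndarray          # (khat, d)
    functional_hpd: np.ndarray           # (khat, d, 2)
    weight_mean: np.ndarray              # (khat,)
    weight_hpd: np.ndarray               # (khat, 2)
    map_partition: np.ndarray            # (N,)
    discard_fraction: float
    n_draws_used: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "khat": self.khat,
            "functional_mean": self.functional_mean.tolist(),
            "functional_hpd": self.functional_hpd.tolist(),
            "weight_mean": self.weight_mean.tolist(),
            "weight_hpd": self.weight_hpd.tolist(),
            "discard_fraction": self.discard_fraction,
            "n_draws_used": self.n_draws_used,
        }


def identify(trace: McmcTrace, khat: int | None = None,
             seed: int | None = None, prob: float = 0.95,
             order_by: int | None = None) -> ClusterSolution:
    """Full identification pipeline: K-hat (posterior mode of K+ unless
    given), k-means relabeling, posterior means / HPD intervals, MAP
    partition.

    ``order_by``: optional column of the relabel functional; clusters are
    reported in decreasing order of its posterior mean (a deterministic
    orientation, e.g. "cluster 1 has the larger Pr(F = 3)").
    """
    if khat is None:
        _, khat = kplus_posterior(trace)
    rel = relabel_draws(trace, khat, seed=seed)
    fmean = rel.functionals.mean(axis=0)
    order = np.arange(khat)
    if order_by is not None:
        order = np.argsort(-fmean[:, order_by], kind="stable")
    inv = np.empty(khat, dtype=int)
    inv[order] = np.arange(khat)
    funcs = rel.functionals[:, order, :]
    weights = rel.weights[:, order]
    alloc = inv[rel.allocations]

    fmean = funcs.mean(axis=0)
    fhpd = np.empty(fmean.shape + (2,))
    for k in range(khat):
        for d in range(fmean.shape[1]):
            fhpd[k, d] = hpd_interval(funcs[:, k, d], prob)
    wmean = weights.mean(axis=0)
    whpd = np.stack([hpd_interval(weights[:, k], prob) for k in range(khat)])
    return ClusterSolution(
        khat=khat, functional_mean=fmean, functional_hpd=fhpd,
        weight_mean=wmean, weight_hpd=whpd,
        map_partition=map_partition(alloc),
        discard_fraction=rel.discard_fraction,
        n_draws_used=rel.kept_index.size,
    )


def adjusted_rand_index(p1, p2) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions."""
    from sklearn.metrics import adjusted_rand_score

    p1, p2 = np.asarray(p1), np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("partitions must have equal length")
    return float(adjusted_rand_score(p1, p2))


def error_rate(partition, truth) -> float:
    """Minimum misclassification proportion over injective label matchings.

    The optimal matching of estimated to true labels is found by the
    Hungarian algorithm on the contingency table.
    """
    from scipy.optimize import linear_sum_assignment

    partition, truth = np.asarray(partition), np.asarray(truth)
    if partition.shape != truth.shape:
        raise ValueError("partitions must have equal length")
    est_labels, est_codes = np.unique(partition, return_inverse=True)
    true_labels, true_codes = np.unique(truth, return_inverse=True)
    table = np.zeros((est_labels.size, true_labels.size))
    np.add.at(table, (est_codes, true_codes), 1.0)
    rows, cols = linear_sum_assignment(-table)
    return 1.0 - table[rows, cols].sum() / partition.size
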