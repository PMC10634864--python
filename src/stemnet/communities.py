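"""Signed-modularity community detection with consensus clustering.

The similarity matrix entering community detection is a correlation matrix,
so it carries negative weights.  The quality function is the asymmetric
signed modularity

    Q(gamma) = (1/v+) sum_ij (w+_ij - gamma p+_ij) delta(s_i, s_j)
             - (1/(v+ + v-)) sum_ij (w-_ij - gamma p-_ij) delta(s_i, s_j)

with w+ / w- the positive part / magnitude of the negative part of the
weights, p+-_ij = s_i s_j / v the configuration-model null within each sign,
v+- the total strength of each sign (sums run over ordered pairs, diagonal
null terms included).  Positive within-community weight is rewarded at full
strength; negative within-community weight is penalized with the weaker
1/(v+ + v-) normalization.  For all-positive graphs Q reduces exactly to
Newman-Girvan modularity at resolution gamma.

Partitions are found with a two-phase Louvain (greedy local moves +
aggregation) written directly against this quality function, stabilized by
consensus clustering over repeated runs: the run-wise co-assignment
(agreement) matrix is thresholded at the mean agreement of label-permuted
null partitions and re-clustered until all runs agree.  Partition stability
across runs is summarized by the z-scored Rand index under the
hypergeometric pair-counting null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix
from .hubs import DegreeMap
from .nodes import NodeTable

__all__ = [
    "SignedGraph",
    "Partition",
    "ConsensusResult",
    "SweepResult",
    "signed_quality",
    "louvain_signed",
    "zrand_score",
    "consensus_partition",
    "gamma_sweep",
    "community_degree_maps",
]


@dataclass
class SignedGraph:
    """Symmetric signed weight matrix with zero diagonal."""

    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w
        self.w_pos = np.clip(w, 0.0, None)
        self.w_neg = np.clip(-w, 0.0, None)
        self.v_pos = float(self.w_pos.sum())   # = 2 m+
        self.v_neg = float(self.w_neg.sum())   # = 2 m-
        if self.v_pos <= 0:
            raise ValueError("graph has no positive weight; "
                             "positive normalization undefined")
        self.s_pos = self.w_pos.sum(axis=1)
        self.s_neg = self.w_neg.sum(axis=1)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_similarity(cls, sim) -> "SignedGraph":
        """Build from a SimilarityMatrix (or array); diagonal is zeroed."""
        values = getattr(sim, "values", sim)
        return cls(weights=np.array(values, float))


@dataclass
class Partition:
    """Community labels (0..k-1, every index used) with the resolution and
    quality at which they were obtained."""

    labels: np.ndarray
    gamma: float
    quality: float = np.nan

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        _, self.labels = np.unique(labels, return_inverse=True)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class ConsensusResult:
    partition: Partition
    n_reps: int
    zrand_mean: float
    zrand_var: float

    @property
    def n_communities(self) -> int:
        return self.partition.n_communities


@dataclass
class SweepResult:
    results: list[ConsensusResult]

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.partition.gamma, r.n_communities, r.zrand_mean, r.zrand_var)
             for r in self.results],
            columns=["gamma", "n_communities", "zrand_mean", "zrand_var"])


def _quality_terms(w: np.ndarray, s: np.ndarray, v: float, labels: np.ndarray,
                   gamma: float) -> float:
    """sum_ij (w_ij - gamma s_i s_j / v) delta(s_i,s_j) / v for one sign.

    Within-community weight totals include any diagonal entries (self-loops
    of aggregated graphs); diagonal null terms are always included.
    """
    if v <= 0:
        return 0.0
    k = int(labels.max()) + 1
    w_in = 0.0
    s_tot = np.bincount(labels, weights=s, minlength=k)
    for c in range(k):
        members = labels == c
        w_in += w[np.ix_(members, members)].sum()
    return (w_in - gamma * float(s_tot @ s_tot) / v) / v


def signed_quality(g: SignedGraph, p: Partition | np.ndarray,
                   gamma: float | None = None) -> float:
    """Evaluate the signed quality function for a partition."""
    if isinstance(p, Partition):
        labels = np.asarray(p.labels, int)
        gamma = p.gamma if gamma is None else gamma
    else:
        labels = np.asarray(p, int)
        if gamma is None:
            raise ValueError("gamma required when passing raw labels")
    if labels.shape != (g.n_nodes,):
        raise ValueError("partition length does not match graph")
    q_pos = _quality_terms(g.w_pos, g.s_pos, g.v_pos, labels, gamma)
    if g.v_neg > 0:
        q_neg_raw = 0.0
        k = int(labels.max()) + 1
        s_tot = np.bincount(labels, weights=g.s_neg, minlength=k)
        for c in range(k):
            members = labels == c
            q_neg_raw += g.w_neg[np.ix_(members, members)].sum()
        q_neg = (q_neg_raw - gamma * float(s_tot @ s_tot) / g.v_neg) \
            / (g.v_pos + g.v_neg)
    else:
        q_neg = 0.0
    return float(q_pos - q_neg)


_GAIN_TOL = 1e-12


def _louvain_level(w_pos: np.ndarray, w_neg: np.ndarray, s_pos: np.ndarray,
                   s_neg: np.ndarray, v_pos: float, v_neg: float,
                   gamma: float, rng: np.random.Generator) -> np.ndarray:
    """Phase 1: greedy local moves on one (possibly aggregated) graph.

    Diagonals of w_pos/w_neg may carry self-loops; they move with the node
    and cancel from every gain, so k_i,c sums exclude them.
    """
    n = w_pos.shape[0]
    kp = w_pos.copy()
    kn = w_neg.copy()
    np.fill_diagonal(kp, 0.0)
    np.fill_diagonal(kn, 0.0)
    labels = np.arange(n)
    S_pos = s_pos.astype(float).copy()   # per-community strength totals
    S_neg = s_neg.astype(float).copy()
    neg_norm = (v_pos + v_neg)
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            a = labels[i]
            ki_pos = np.bincount(labels, weights=kp[i], minlength=n)
            ki_neg = np.bincount(labels, weights=kn[i], minlength=n)
            # gain of moving i from its community a into community c
            gain_pos = 2.0 * (ki_pos - ki_pos[a]) \
                - 2.0 * gamma * s_pos[i] * (S_pos - S_pos[a] + s_pos[i]) / v_pos
            gain_pos[a] = 0.0
            gain = gain_pos / v_pos
            if v_neg > 0:
                gain_neg = 2.0 * (ki_neg - ki_neg[a]) \
                    - 2.0 * gamma * s_neg[i] * (S_neg - S_neg[a] + s_neg[i]) / v_neg
                gain_neg[a] = 0.0
                gain = gain - gain_neg / neg_norm
            best = int(np.argmax(gain))
            if gain[best] > _GAIN_TOL and best != a:
                labels[i] = best
                S_pos[a] -= s_pos[i]
                S_pos[best] += s_pos[i]
                S_neg[a] -= s_neg[i]
                S_neg[best] += s_neg[i]
                improved = True
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def _aggregate(w: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    ind = np.zeros((w.shape[0], k))
    ind[np.arange(w.shape[0]), labels] = 1.0
    return ind.T @ w @ ind


def louvain_signed(g: SignedGraph, gamma: float = 1.0,
                   seed: int | np.random.Generator = 0) -> Partition:
    """Two-phase Louvain maximization of the signed quality function.

    Node visitation order is shuffled from ``seed`` each sweep; among
    equal-gain moves the node keeps its current community.  The returned
    quality is an exact re-evaluation of :func:`signed_quality` on the final
    labels.
    """
    rng = np.random.default_rng(seed)
    w_pos, w_neg = g.w_pos.copy(), g.w_neg.copy()
    s_pos, s_neg = g.s_pos.copy(), g.s_neg.copy()
    labels_full = np.arange(g.n_nodes)
    while True:
        labels = _louvain_level(w_pos, w_neg, s_pos, s_neg,
                                g.v_pos, g.v_neg, gamma, rng)
        k = int(labels.max()) + 1
        labels_full = labels[labels_full]
        if k == w_pos.shape[0]:
            break
        w_pos = _aggregate(w_pos, labels, k)
        w_neg = _aggregate(w_neg, labels, k)
        s_pos = w_pos.sum(axis=1)
        s_neg = w_neg.sum(axis=1)
    part = Partition(labels=labels_full, gamma=gamma)
    part.quality = signed_quality(g, part)
    return part


def _pair_count(sizes: np.ndarray) -> float:
    return float((sizes * (sizes - 1) // 2).sum())


def zrand_score(p1: Partition | np.ndarray, p2: Partition | np.ndarray) -> float:
    """z-scored Rand index of two partitions (hypergeometric pair-count null).

    z = (w - E[w]) / sd(w) where w is the number of node pairs co-assigned in
    both partitions and the moments are taken over random permutations of one
    partition's labels.  Degenerate cases (a partition with zero or all pairs
    co-assigned in both) have sd(w) = 0 and return NaN (flagged undefined).
    """
    x = np.asarray(p1.labels if isinstance(p1, Partition) else p1, int)
    y = np.asarray(p2.labels if isinstance(p2, Partition) else p2, int)
    if x.shape != y.shape:
        raise ValueError("partitions must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("z-Rand needs at least 4 nodes")
    kx, x = np.unique(x, return_inverse=True)
    ky, y = np.unique(y, return_inverse=True)
    cont = np.zeros((kx.size, ky.size))
    np.add.at(cont, (x, y), 1.0)
    a = cont.sum(axis=1)
    b = cont.sum(axis=0)
    big_m = n * (n - 1) / 2.0
    m1 = _pair_count(a.astype(int))
    m2 = _pair_count(b.astype(int))
    w = _pair_count(cont.astype(int).ravel())
    mu = m1 * m2 / big_m
    c1 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * m1 + 4 * np.sum(a**3)
    c2 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * m2 + 4 * np.sum(b**3)
    var = (big_m / 16.0
           - (4 * m1 - 2 * big_m)**2 * (4 * m2 - 2 * big_m)**2 / (256.0 * big_m**2)
           + c1 * c2 / (16.0 * n * (n - 1) * (n - 2))
           + ((4 * m1 - 2 * big_m)**2 - 4 * c1 - 4 * big_m)
           * ((4 * m2 - 2 * big_m)**2 - 4 * c2 - 4 * big_m)
           / (64.0 * n * (n - 1) * (n - 2) * (n - 3)))
    if var <= 0:
        return float("nan")
    return float((w - mu) / np.sqrt(var))


def _pairwise_zrand_stats(parts: list[np.ndarray]) -> tuple[float, float]:
    vals = []
    for i in range(len(parts)):
        for j in range(i + 1, len(parts)):
            vals.append(zrand_score(parts[i], parts[j]))
    vals = np.asarray(vals, float)
    if np.all(np.isnan(vals)):
        return float("nan"), float("nan")
    mean = float(np.nanmean(vals))
    var = float(np.nanvar(vals, ddof=1)) if vals.size > 1 else 0.0
    return mean, var


def _agreement(parts: np.ndarray) -> np.ndarray:
    """Fraction of runs co-assigning each node pair; parts is (reps, n)."""
    reps, n = parts.shape
    agree = np.zeros((n, n))
    for row in parts:
        agree += row[:, None] == row[None, :]
    return agree / reps


def consensus_partition(g: SignedGraph, gamma: float, n_reps: int = 250,
                        seed: int = 0, n_null: int = 100,
                        max_iter: int = 100) -> ConsensusResult:
    """Consensus clustering over repeated Louvain runs.

    The agreement matrix of the runs is thresholded at the mean agreement of
    label-permuted null partitions, and the thresholded matrix (a positive
    graph) is re-clustered at gamma = 1 until all runs return the same
    partition.  Also reports the mean and variance of the pairwise z-Rand
    over the original runs.
    """
    if n_reps < 2:
        raise ValueError("consensus needs n_reps >= 2")
    rng = np.random.default_rng(seed)
    parts = np.stack([louvain_signed(g, gamma, rng).labels
                      for _ in range(n_reps)])
    zmean, zvar = _pairwise_zrand_stats(list(parts))

    current = parts
    prev_agree = None
    for _ in range(max_iter):
        if all(np.array_equal(current[0], row) for row in current[1:]):
            final = Partition(labels=current[0], gamma=gamma)
            final.quality = signed_quality(g, final)
            return ConsensusResult(partition=final, n_reps=n_reps,
                                   zrand_mean=zmean, zrand_var=zvar)
        agree = _agreement(current)
        binary = np.all((agree < 1e-9) | (agree > 1 - 1e-9))
        cycling = prev_agree is not None and np.allclose(agree, prev_agree)
        if binary or cycling:
            # runs disagree only through label bookkeeping or an order-dependent
            # tie cycle: the stable consensus is the set of node groups that are
            # always co-assigned
            from scipy.sparse.csgraph import connected_components
            _, labels = connected_components((agree > 1 - 1e-9).astype(int),
                                             directed=False)
            final = Partition(labels=labels, gamma=gamma)
            final.quality = signed_quality(g, final)
            return ConsensusResult(partition=final, n_reps=n_reps,
                                   zrand_mean=zmean, zrand_var=zvar)
        prev_agree = agree
        # null threshold: mean co-assignment of label-permuted partitions
        null_vals = np.empty(n_null)
        for t in range(n_null):
            row = current[t % len(current)]
            perm = row[rng.permutation(row.size)]
            null_vals[t] = float(np.mean(perm[:, None] == perm[None, :]))
        thr = float(null_vals.mean())
        pruned = np.where(agree > thr, agree, 0.0)
        np.fill_diagonal(pruned, 0.0)
        if pruned.sum() == 0:
            # nothing survives the null threshold: all singletons is the consensus
            final = Partition(labels=np.arange(g.n_nodes), gamma=gamma)
            final.quality = signed_quality(g, final)
            return ConsensusResult(partition=final, n_reps=n_reps,
                                   zrand_mean=zmean, zrand_var=zvar)
        agree_graph = SignedGraph(weights=pruned)
        current = np.stack([louvain_signed(agree_graph, 1.0, rng).labels
                            for _ in range(n_reps)])
    raise RuntimeError(
        f"consensus failed to converge in {max_iter} iterations "
        f"(gamma={gamma}, n_reps={n_reps}); last agreement matrix had "
        f"mean {float(_agreement(current).mean()):.3f}")


DEFAULT_GAMMA_GRID = np.round(np.arange(0.1, 6.0 + 1e-9, 0.1), 1)


def gamma_sweep(g: SignedGraph, gammas: np.ndarray | None = None,
                n_reps: int = 250, seed: int = 0) -> SweepResult:
    """Consensus clustering across a resolution sweep (default 0.1-6.0)."""
    if gammas is None:
        gammas = DEFAULT_GAMMA_GRID
    gammas = np.asarray(gammas, float)
    if gammas.size == 0:
        raise ValueError("gamma grid must be nonempty")
    seeds = np.random.SeedSequence(seed).spawn(gammas.size)
    results = [consensus_partition(g, float(gamma), n_reps=n_reps,
                                   seed=np.random.default_rng(s))
               for gamma, s in zip(gammas, seeds)]
    return SweepResult(results=results)


def community_degree_maps(fc: ConnectivityMatrix, partition: Partition,
                          nodes: NodeTable) -> dict[int, DegreeMap]:
    """Per-community cortical degree maps: for community c, the sum of each
    cortical region's FC with the brainstem nuclei assigned to c (raw FC)."""
    ctx, bs = nodes.cortex_idx, nodes.brainstem_idx
    labels = np.asarray(partition.labels, int)
    if labels.shape != bs.shape:
        raise ValueError("partition must cover exactly the brainstem nodes")
    maps = {}
    for c in range(partition.n_communities):
        members = bs[labels == c]
        if members.size == 0:
            raise ValueError(f"community {c} is empty")
        values = fc.values[np.ix_(ctx, members)].sum(axis=1)
        maps[c] = DegreeMap(values=values, seed_idx=members, target_idx=ctx)
    return maps
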