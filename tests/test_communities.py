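"""Signed modularity, Louvain, z-Rand and consensus clustering."""

from itertools import combinations, permutations

import numpy as np
import networkx as nx
import pytest

import stemnet as sn
from stemnet.communities import _agreement


def random_signed(n, rng, scale=1.0):
    w = rng.normal(scale=scale, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return sn.SignedGraph(w)


def brute_quality(w, labels, gamma):
    """Loop-based reference implementation of the signed quality function."""
    wp = np.clip(w, 0, None)
    wn = np.clip(-w, 0, None)
    sp, sn_ = wp.sum(1), wn.sum(1)
    vp, vn = wp.sum(), wn.sum()
    qp = qn = 0.0
    n = len(labels)
    for i in range(n):
        for j in range(n):
            if labels[i] != labels[j]:
                continue
            qp += wp[i, j] - gamma * sp[i] * sp[j] / vp
            if vn > 0:
                qn += wn[i, j] - gamma * sn_[i] * sn_[j] / vn
    q = qp / vp
    if vn > 0:
        q -= qn / (vp + vn)
    return q


class TestSignedQuality:
    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = random_signed(rng.integers(5, 9), rng)
            for _ in range(5):
                labels = rng.integers(0, 3, g.n_nodes)
                gamma = float(rng.uniform(0.2, 3.0))
                assert sn.signed_quality(g, labels, gamma) == pytest.approx(
                    brute_quality(g.weights, labels, gamma), abs=1e-12)

    def test_reduces_to_newman_on_positive_graphs(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(5, 11))
            w = np.abs(rng.normal(size=(n, n)))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            labels = rng.integers(0, 3, n)
            gamma = float(rng.uniform(0.3, 2.5))
            ref = nx.algorithms.community.modularity(
                nx.from_numpy_array(w),
                [set(np.flatnonzero(labels == c)) for c in np.unique(labels)],
                weight="weight", resolution=gamma)
            assert sn.signed_quality(sn.SignedGraph(w), labels, gamma) == \
                pytest.approx(ref, abs=1e-12)

    def test_two_cliques(self):
        w = np.zeros((6, 6))
        for block in (range(3), range(3, 6)):
            for a, b in combinations(block, 2):
                w[a, b] = w[b, a] = 1.0
        q = sn.signed_quality(sn.SignedGraph(w), np.array([0, 0, 0, 1, 1, 1]), 1.0)
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_singleton_partition_closed_form(self):
        rng = np.random.default_rng(2)
        g = random_signed(6, rng)
        gamma = 1.7
        expect = -gamma * (np.sum(g.s_pos**2) / g.v_pos**2
                           - np.sum(g.s_neg**2) / (g.v_neg * (g.v_pos + g.v_neg)))
        assert sn.signed_quality(g, np.arange(6), gamma) == pytest.approx(expect, abs=1e-12)

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(3)
        g = random_signed(7, rng)
        labels = rng.integers(0, 3, 7)
        perm = rng.permutation(7)
        g2 = sn.SignedGraph(g.weights[np.ix_(perm, perm)])
        assert sn.signed_quality(g, labels, 1.3) == pytest.approx(
            sn.signed_quality(g2, labels[perm], 1.3), abs=1e-12)

    def test_all_negative_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sn.SignedGraph(-np.ones((3, 3)) + np.eye(3) * 1)


def all_partitions(n):
    def rec(p):
        if len(p) == n:
            yield list(p)
            return
        for c in range(max(p) + 2):
            yield from rec(p + [c])
    yield from rec([0])


class TestLouvain:
    def test_planted_signed_blocks_recovered(self):
        w = np.full((12, 12), -0.2)
        w[:6, :6] = 0.8
        w[6:, 6:] = 0.8
        np.fill_diagonal(w, 0.0)
        g = sn.SignedGraph(w)
        truth = np.array([0] * 6 + [1] * 6)
        for seed in range(25):
            part = sn.louvain_signed(g, 1.0, seed)
            assert part.n_communities == 2
            assert np.array_equal(part.labels, truth) or \
                np.array_equal(part.labels, 1 - truth)

    def test_quality_is_exact_reevaluation(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            g = random_signed(10, rng)
            part = sn.louvain_signed(g, 1.5, seed)
            assert part.quality == sn.signed_quality(g, part)

    def test_attains_bruteforce_optimum_small_graphs(self):
        parts = [np.array(p) for p in all_partitions(6)]
        rng = np.random.default_rng(5)
        hits = 0
        for trial in range(20):
            g = random_signed(6, rng)
            best = max(sn.signed_quality(g, p, 1.0) for p in parts)
            got = max(sn.louvain_signed(g, 1.0, s).quality for s in range(20))
            hits += got == pytest.approx(best, abs=1e-10)
        assert hits >= 19

    def test_gamma_zero_positive_graph_single_community(self):
        rng = np.random.default_rng(6)
        w = np.abs(rng.normal(size=(8, 8)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        part = sn.louvain_signed(sn.SignedGraph(w), 1e-9, 0)
        assert part.n_communities == 1


class TestZRand:
    def test_exact_enumeration_moments(self):
        # exact E[w] and Var[w] over all relabelings of 6 nodes
        rng = np.random.default_rng(7)
        for _ in range(3):
            x = rng.integers(0, 3, 6)
            y = rng.integers(0, 3, 6)
            if len(set(x)) == 1 or len(set(y)) == 1:
                continue
            pairs = list(combinations(range(6), 2))
            ws = []
            for perm in permutations(range(6)):
                yp = y[list(perm)]
                ws.append(sum((x[i] == x[j]) and (yp[i] == yp[j]) for i, j in pairs))
            ws = np.array(ws, float)
            w_obs = sum((x[i] == x[j]) and (y[i] == y[j]) for i, j in pairs)
            z_exact = (w_obs - ws.mean()) / ws.std()
            assert sn.zrand_score(x, y) == pytest.approx(z_exact, abs=1e-10)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 4, 20)
        y = rng.integers(0, 4, 20)
        relabel = np.array([2, 0, 3, 1])
        assert sn.zrand_score(x, y) == pytest.approx(
            sn.zrand_score(x, relabel[y]), abs=1e-12)

    def test_identical_nontrivial_partitions_positive(self):
        x = np.array([0, 0, 1, 1, 2, 2, 2, 0])
        assert sn.zrand_score(x, x) > 0

    def test_degenerate_flagged_nan(self):
        assert np.isnan(sn.zrand_score(np.zeros(6, int), np.zeros(6, int)))


class TestConsensus:
    def planted_graph(self, n=30, k=3, rng=None):
        labels = np.arange(n) % k
        w = np.where(labels[:, None] == labels[None, :], 0.9, -0.3)
        w = w + (rng.normal(scale=0.02, size=(n, n)) if rng is not None else 0.0)
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        return sn.SignedGraph(w), labels

    def test_recovers_planted_blocks_exactly(self):
        from sklearn.metrics import adjusted_rand_score
        g, truth = self.planted_graph(rng=np.random.default_rng(9))
        out = sn.consensus_partition(g, gamma=1.0, n_reps=30, seed=0)
        assert adjusted_rand_score(truth, out.partition.labels) == 1.0
        assert out.zrand_var == pytest.approx(0.0, abs=1e-12)
        assert out.n_communities == 3

    def test_agreement_matrix_definition(self):
        parts = np.array([[0, 0, 1, 1], [0, 1, 1, 0]])
        agree = _agreement(parts)
        assert agree[0, 1] == 0.5 and agree[2, 3] == 0.5 and agree[0, 3] == 0.5
        assert agree[0, 2] == 0.0

    def test_seeded_determinism(self):
        g, _ = self.planted_graph(rng=np.random.default_rng(10))
        a = sn.consensus_partition(g, 1.0, n_reps=10, seed=3)
        b = sn.consensus_partition(g, 1.0, n_reps=10, seed=3)
        assert np.array_equal(a.partition.labels, b.partition.labels)
        assert a.zrand_mean == b.zrand_mean

    def test_n_reps_lower_bound(self):
        g, _ = self.planted_graph(rng=np.random.default_rng(11))
        with pytest.raises(ValueError, match="n_reps"):
            sn.consensus_partition(g, 1.0, n_reps=1)


class TestGammaSweep:
    def test_table_shape_and_default_grid(self):
        assert len(sn.communities.DEFAULT_GAMMA_GRID) == 60
        assert sn.communities.DEFAULT_GAMMA_GRID[0] == 0.1
        assert sn.communities.DEFAULT_GAMMA_GRID[-1] == 6.0

    def test_sweep_rows_and_hierarchy(self):
        # nested planted hierarchy: 2 super-blocks, each of 2 sub-blocks
        n = 16
        sub = np.arange(n) // 4
        sup = sub // 2
        w = np.where(sup[:, None] == sup[None, :], 0.3, -0.4)
        w = np.where(sub[:, None] == sub[None, :], 0.9, w)
        np.fill_diagonal(w, 0.0)
        g = sn.SignedGraph(w)
        sweep = sn.gamma_sweep(g, gammas=[0.5, 1.5, 3.0], n_reps=20, seed=0)
        tab = sweep.table
        assert list(tab["gamma"]) == [0.5, 1.5, 3.0]
        ks = list(tab["n_communities"])
        assert ks == sorted(ks)            # nondecreasing in gamma
        assert ks[0] <= 2 and ks[-1] >= 4


class TestCommunityDegreeMaps:
    def test_toy_sums_and_additivity(self, small_dataset):
        import pandas as pd
        block = np.array([[0.1, 0.2, 0.3, -0.1],
                          [0.0, 0.5, -0.2, 0.4],
                          [0.3, 0.1, 0.2, 0.2]])
        nc, nb = block.shape
        v = np.eye(nc + nb)
        v[:nc, nc:] = block
        v[nc:, :nc] = block.T
        fc = sn.ConnectivityMatrix(v)
        df = pd.DataFrame({
            "name": [f"c{i}" for i in range(nc)] + [f"b{i}" for i in range(nb)],
            "structure": ["cortex"] * nc + ["brainstem"] * nb,
            "hemisphere": "midline", "x": 0.0, "y": 0.0, "z": 0.0})
        nodes = sn.NodeTable(df)
        part = sn.Partition(labels=np.array([0, 0, 1, 1]), gamma=1.0)
        maps = sn.community_degree_maps(fc, part, nodes)
        assert np.allclose(maps[0].values, block[:, :2].sum(1))
        assert np.allclose(maps[1].values, block[:, 2:].sum(1))
        total = sn.weighted_degree(fc, seed_idx=nodes.brainstem_idx,
                                   target_idx=nodes.cortex_idx).values
        assert np.allclose(maps[0].values + maps[1].values, total, atol=1e-15)

    def test_single_community_equals_degree(self, small_dataset):
        fc, nodes = small_dataset["fc"], small_dataset["nodes"]
        part = sn.Partition(labels=np.zeros(nodes.n_brainstem, int), gamma=1.0)
        maps = sn.community_degree_maps(fc, part, nodes)
        total = sn.weighted_degree(fc, nodes.brainstem_idx, nodes.cortex_idx).values
        assert np.allclose(maps[0].values, total)
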