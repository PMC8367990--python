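"""Thresholding: edge density, global vs local (k-NNG) construction."""

import math

import numpy as np
import pytest

import modbrain as mb
from modbrain.community import Partition

from conftest import restored_edge_toy


def complete_adjacency(n):
    a = np.ones((n, n), dtype=int) - np.eye(n, dtype=int)
    return a


class TestEdgeDensity:
    def test_empty_graph_is_zero(self):
        assert mb.edge_density(np.zeros((10, 10), dtype=int)) == 0.0

    def test_complete_graph_is_hundred(self):
        assert mb.edge_density(complete_adjacency(451)) == pytest.approx(100.0)

    def test_direct_substitution(self):
        # 10 nodes, 9 edges along a path: 2*9/90*100 = 20%
        a = np.zeros((10, 10), dtype=int)
        for i in range(9):
            a[i, i + 1] = a[i + 1, i] = 1
        assert mb.edge_density(a) == pytest.approx(20.0)

    @pytest.mark.parametrize("bad", [
        np.ones((3, 4)),                       # not square
        np.array([[0, 1], [0, 0]]),            # asymmetric
        np.array([[1, 1], [1, 0]]),            # nonzero diagonal
        np.array([[0, 2], [2, 0]]),            # not 0/1
    ])
    def test_invalid_inputs_raise(self, bad):
        with pytest.raises(ValueError):
            mb.edge_density(bad)


class TestGlobalThreshold:
    def test_full_density_keeps_all_positive_pairs(self):
        rng = np.random.default_rng(0)
        w = np.triu(rng.uniform(0.1, 1, (8, 8)), 1)
        w[0, 1] = 0.0  # an exact-zero pair must never become an edge
        conn = mb.WeightedConnectome(w + w.T)
        net = mb.global_threshold(conn, 100.0)
        assert net.n_edges == 8 * 7 // 2 - 1
        assert net.adjacency[0, 1] == 0

    def test_sort_and_count_oracle(self):
        rng = np.random.default_rng(1)
        w = np.triu(rng.uniform(0.01, 1, (10, 10)), 1)
        conn = mb.WeightedConnectome(w + w.T)
        net = mb.global_threshold(conn, 20.0)
        # 20% of 45 pairs -> 9 largest-weight edges
        iu, ju = np.triu_indices(10, 1)
        order = np.argsort(-conn.weights[iu, ju])
        expected = {(iu[k], ju[k]) for k in order[:9]}
        assert net.edge_set() == expected
        assert net.n_edges == 9
        tau = min(conn.weights[i, j] for i, j in expected)
        assert net.threshold_tau == pytest.approx(tau)

    def test_tied_weights_break_by_node_index(self):
        w = np.zeros((4, 4))
        # three edges with identical weight straddle a 2-edge cutoff
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            w[i, j] = w[j, i] = 0.5
        conn = mb.WeightedConnectome(w)
        net = mb.global_threshold(conn, 2 * 2 / (4 * 4 - 4) * 100 + 1e-9)
        assert net.edge_set() == {(0, 1), (0, 2)}

    def test_density_out_of_range(self):
        conn = mb.WeightedConnectome(np.zeros((4, 4)))
        for bad in (0.0, -1.0, 101.0):
            with pytest.raises(ValueError):
                mb.global_threshold(conn, bad)

    def test_containment_monotone_in_density(self):
        rng = np.random.default_rng(2)
        w = np.triu(rng.uniform(0.01, 1, (20, 20)), 1)
        conn = mb.WeightedConnectome(w + w.T)
        prev = set()
        for d in (5, 10, 20, 50, 100):
            cur = mb.global_threshold(conn, d).edge_set()
            assert prev <= cur
            prev = cur


def oracle_knng(w, k):
    """Union k-nearest-neighbour graph by direct per-node enumeration."""
    n = w.shape[0]
    edges = set()
    for i in range(n):
        nbrs = sorted(
            (j for j in range(n) if j != i and w[i, j] > 0),
            key=lambda j: (-w[i, j], j),
        )
        for j in nbrs[:k]:
            edges.add((min(i, j), max(i, j)))
    return edges


def oracle_local_threshold(w, density):
    """Direct k-NNG enumeration + descending-weight augmentation."""
    n = w.shape[0]
    t = math.floor(density * (n * n - n) / 200.0)

    def knng(k):
        return oracle_knng(w, k)

    if len(knng(1)) > t:
        raise ValueError("below 1-NNG floor")
    k = 1
    while k < n and len(knng(k + 1)) <= t:
        k += 1
    edges = knng(k)
    for e in sorted(knng(k + 1) - edges, key=lambda e: (-w[e[0], e[1]], e)):
        if len(edges) >= t:
            break
        edges.add(e)
    return edges, k


class TestLocalThreshold:
    def test_full_density_matches_global(self):
        rng = np.random.default_rng(3)
        w = np.triu(rng.uniform(0.01, 1, (9, 9)), 1)
        conn = mb.WeightedConnectome(w + w.T)
        loc = mb.local_threshold(conn, 100.0)
        glo = mb.global_threshold(conn, 100.0)
        assert np.array_equal(loc.adjacency, glo.adjacency)

    def test_weak_hub_edge_kept_only_by_local(self):
        conn = restored_edge_toy()
        density = 7 * 200 / (7 * 7 - 7) + 1e-9  # exactly 7 edges
        loc = mb.local_threshold(conn, density)
        glo = mb.global_threshold(conn, density)
        assert (0, 6) in loc.edge_set()
        assert (0, 6) not in glo.edge_set()
        assert loc.n_edges == glo.n_edges == 7
        # min degree >= k_base >= 1: node 6 keeps its strongest neighbour
        assert loc.adjacency.sum(axis=0).min() >= 1

    def test_min_degree_at_least_one(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            w = np.triu(rng.uniform(0.01, 1, (12, 12)), 1)
            conn = mb.WeightedConnectome(w + w.T)
            floor_net = mb.local_threshold(conn, 25.0)
            assert floor_net.adjacency.sum(axis=0).min() >= 1

    def test_density_below_floor_signals_minimum(self):
        rng = np.random.default_rng(5)
        w = np.triu(rng.uniform(0.5, 1, (30, 30)), 1)
        conn = mb.WeightedConnectome(w + w.T)
        with pytest.raises(mb.DensityTooLowError) as err:
            mb.local_threshold(conn, 0.5)
        assert err.value.minimum > 0.5

    def test_matches_bruteforce_oracle_on_small_graphs(self):
        rng = np.random.default_rng(6)
        for trial in range(40):
            n = int(rng.integers(4, 7))
            n_pairs = n * (n - 1) // 2
            w = np.zeros((n, n))
            iu, ju = np.triu_indices(n, 1)
            vals = rng.permutation(n_pairs) + 1.0  # distinct weights
            w[iu, ju] = vals / (n_pairs + 1)
            w = w + w.T
            conn = mb.WeightedConnectome(w)
            t = int(rng.integers(max(1, n - 1), n_pairs + 1))
            density = min(100.0, (t + 0.5) * 200.0 / (n * n - n))
            try:
                expected, k_expected = oracle_local_threshold(w, density)
            except ValueError:
                continue
            net = mb.local_threshold(conn, density)
            assert net.edge_set() == expected
            # k_base is a valid base order: its k-NNG fits within the target
            assert net.k_base >= 1
            assert oracle_knng(w, net.k_base) <= expected

    def test_density_agreement_with_global(self):
        rng = np.random.default_rng(7)
        w = np.triu(rng.uniform(0.01, 1, (25, 25)), 1)
        conn = mb.WeightedConnectome(w + w.T)
        for d in (20.0, 40.0, 70.0):
            loc = mb.local_threshold(conn, d)
            glo = mb.global_threshold(conn, d)
            one_edge = 2.0 / (25 * 25 - 25) * 100
            assert abs(loc.realized_density - glo.realized_density) <= one_edge

    def test_contains_one_nng(self):
        rng = np.random.default_rng(8)
        w = np.triu(rng.uniform(0.01, 1, (15, 15)), 1)
        conn = mb.WeightedConnectome(w + w.T)
        net = mb.local_threshold(conn, 30.0)
        edges = net.edge_set()
        for i in range(15):
            best = np.argmax(conn.weights[i])
            assert (min(i, best), max(i, best)) in edges


class TestWeightedMask:
    def test_identity_and_zero_masks(self):
        rng = np.random.default_rng(9)
        w = np.triu(rng.uniform(0.01, 1, (6, 6)), 1)
        conn = mb.WeightedConnectome(w + w.T)
        ones = mb.BinaryNetwork(complete_adjacency(6), "global", 100.0)
        zeros = mb.BinaryNetwork(np.zeros((6, 6), dtype=int), "global", 1.0)
        assert np.allclose(mb.weighted_mask(conn, ones).weights, conn.weights)
        assert not mb.weighted_mask(conn, zeros).weights.any()

    def test_elementwise_oracle_four_nodes(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.8
        w[2, 3] = w[3, 2] = 0.4
        w[0, 2] = w[2, 0] = 0.6
        conn = mb.WeightedConnectome(w)
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = 1
        a[2, 3] = a[3, 2] = 1
        net = mb.BinaryNetwork(a, "global", 33.3)
        masked = mb.weighted_mask(conn, net).weights
        assert masked[0, 1] == 0.8 and masked[2, 3] == 0.4
        assert masked[0, 2] == 0.0
        assert (masked != 0).sum() == 4  # two undirected edges

    def test_shape_mismatch_raises(self):
        conn = mb.WeightedConnectome(np.zeros((4, 4)))
        net = mb.BinaryNetwork(np.zeros((5, 5), dtype=int), "global", 1.0)
        with pytest.raises(ValueError):
            mb.weighted_mask(conn, net)


class TestAddedEdgeClasses:
    def test_identical_networks_all_zero(self):
        conn = restored_edge_toy()
        net = mb.global_threshold(conn, 50.0)
        part = Partition(np.zeros(7, dtype=int))
        counts = mb.added_edge_classes(net, net, part)
        assert all(v == 0 for v in counts.values())

    def test_restored_intra_edge_counted(self):
        conn = restored_edge_toy()
        density = 7 * 200 / 42 + 1e-9
        loc = mb.local_threshold(conn, density)
        glo = mb.global_threshold(conn, density)
        part = Partition(np.array([0, 0, 0, 1, 1, 1, 0]))  # node 6 with module A
        counts = mb.added_edge_classes(loc, glo, part)
        assert counts["intra_added_by_local"] == 1  # edge (0, 6)
        assert counts["inter_only_global"] == 1  # bridge (2, 3)
        sym_diff = loc.edge_set() ^ glo.edge_set()
        assert sum(counts.values()) == len(sym_diff)

    def test_density_mismatch_raises(self):
        conn = restored_edge_toy()
        part = Partition(np.zeros(7, dtype=int))
        with pytest.raises(ValueError):
            mb.added_edge_classes(
                mb.local_threshold(conn, 35.0), mb.global_threshold(conn, 20.0), part
            )
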