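"""Graph metrics vs exhaustive oracles; thresholding; rewiring; small-world."""

import networkx as nx
import numpy as np
import pytest

from oracles import (
    bf_betweenness,
    bf_char_path_length,
    bf_clustering,
    bf_global_efficiency,
    bf_local_efficiency,
)

from nirsconn.connectivity import BinaryNetwork, ConnectivityMatrix
from nirsconn.errors import InvalidParameterError
from nirsconn.graph_metrics import (
    GraphMetricProfile,
    betweenness,
    char_path_length,
    clustering_coefficient,
    density_threshold,
    global_efficiency,
    local_efficiency,
    metric_sweep,
    nodal_group_comparison,
    rewire_preserving_degree,
    small_worldness,
)


def _net(adj):
    return BinaryNetwork(np.asarray(adj, dtype=int), threshold_used=0.0)


def _complete(n):
    return _net(np.ones((n, n), dtype=int) - np.eye(n, dtype=int))


def _path3():
    return _net([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


def _star5():
    a = np.zeros((5, 5), dtype=int)
    a[0, 1:] = a[1:, 0] = 1
    return _net(a)


class TestClosedFormCases:
    def test_complete_graph_k4(self):
        k4 = _complete(4)
        assert clustering_coefficient(k4) == pytest.approx(1.0)
        assert global_efficiency(k4) == pytest.approx(1.0)
        assert char_path_length(k4) == pytest.approx(1.0)
        mean_el, nodal_el = local_efficiency(k4)
        assert mean_el == pytest.approx(1.0)
        assert np.allclose(nodal_el, 1.0)

    def test_star_has_no_triangles_or_local_structure(self):
        s = _star5()
        assert clustering_coefficient(s) == 0.0
        assert np.allclose(local_efficiency(s)[1], 0.0)
        # every shortest path between leaves passes through the hub
        bc = betweenness(s)
        assert bc[0] == pytest.approx(1.0)
        assert np.allclose(bc[1:], 0.0)

    def test_path_p3_values(self):
        p3 = _path3()
        assert global_efficiency(p3) == pytest.approx(5.0 / 6.0)
        assert char_path_length(p3) == pytest.approx(4.0 / 3.0)
        bc = betweenness(p3)
        assert bc[1] == pytest.approx(1.0)   # ordered-pair convention
        assert bc[0] == bc[2] == 0.0
        # halved (unordered) convention available as an option
        assert betweenness(p3, ordered_pairs=False)[1] == pytest.approx(0.5)

    def test_disjoint_edges_path_length_counts_connected_pairs_only(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        assert char_path_length(_net(a)) == pytest.approx(1.0)

    def test_empty_graph_conventions(self):
        empty = _net(np.zeros((5, 5), dtype=int))
        assert global_efficiency(empty) == 0.0
        assert np.isnan(char_path_length(empty))


def _atlas_graphs():
    """All non-isomorphic simple graphs on 1..6 nodes."""
    return [g for g in nx.graph_atlas_g() if 1 <= g.number_of_nodes() <= 6]


def test_metrics_match_bruteforce_on_random_small_graphs(rng):
    # spot-check on arbitrary 6-node graphs (full atlas check is in acceptance)
    for _ in range(25):
        a = (rng.uniform(size=(6, 6)) < 0.4).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        net = _net(a)
        assert clustering_coefficient(net) == pytest.approx(bf_clustering(a), abs=1e-12)
        assert global_efficiency(net) == pytest.approx(bf_global_efficiency(a), abs=1e-12)
        lp = char_path_length(net)
        lp_o = bf_char_path_length(a)
        assert (np.isnan(lp) and np.isnan(lp_o)) or lp == pytest.approx(lp_o, abs=1e-12)
        assert np.allclose(local_efficiency(net)[1], bf_local_efficiency(a), atol=1e-12)
        assert np.allclose(betweenness(net), bf_betweenness(a), atol=1e-12)


def test_metric_invariance_under_node_relabeling(rng):
    a = (rng.uniform(size=(8, 8)) < 0.4).astype(int)
    a = np.triu(a, 1)
    a = a + a.T
    perm = rng.permutation(8)
    ap = a[np.ix_(perm, perm)]
    assert clustering_coefficient(_net(a)) == pytest.approx(clustering_coefficient(_net(ap)))
    assert global_efficiency(_net(a)) == pytest.approx(global_efficiency(_net(ap)))
    assert np.allclose(betweenness(_net(a))[perm], betweenness(_net(ap)))
    assert np.allclose(local_efficiency(_net(a))[1][perm], local_efficiency(_net(ap))[1])


class TestDensityThreshold:
    def _mat(self, rng):
        v = rng.uniform(-1, 1, size=(22, 22))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        return ConnectivityMatrix(v)

    def test_edge_count_formula(self, rng):
        m = self._mat(rng)
        assert density_threshold(m, 0.9).n_edges == int(np.floor(0.9 * 231))  # 207
        assert density_threshold(m, 0.5).n_edges == int(np.floor(0.5 * 231))
        assert density_threshold(m, 1.0 / 231 - 1e-9).n_edges == 0

    def test_nested_edge_sets(self, rng):
        m = self._mat(rng)
        prev = density_threshold(m, 0.1).adjacency
        for T in np.arange(0.2, 1.0, 0.1):
            cur = density_threshold(m, float(T)).adjacency
            assert np.all(prev <= cur)
            prev = cur

    def test_tie_break_deterministic(self):
        v = np.full((22, 22), 0.5)
        np.fill_diagonal(v, 1.0)
        m = ConnectivityMatrix(v)
        a = density_threshold(m, 0.1)
        b = density_threshold(m, 0.1)
        assert np.array_equal(a.adjacency, b.adjacency)
        assert a.n_edges == 23  # floor(0.1 * 231)
        # lexicographically first pairs kept: (0,1), (0,2), ...
        assert a.adjacency[0, 1] == 1 and a.adjacency[0, 21] == 1

    def test_invalid_threshold(self, rng):
        with pytest.raises(InvalidParameterError):
            density_threshold(self._mat(rng), 1.5)


class TestRewiring:
    def test_degree_sequence_preserved(self, rng):
        a = (rng.uniform(size=(22, 22)) < 0.3).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        net = _net(a)
        for seed in range(5):
            null = rewire_preserving_degree(net, seed=seed)
            assert np.array_equal(null.degrees, net.degrees)
            assert not np.any(np.diag(null.adjacency))

    def test_triangle_returned_unchanged(self):
        k3 = _complete(3)
        null = rewire_preserving_degree(k3, seed=0)
        assert np.array_equal(null.adjacency, k3.adjacency)
        assert null.degenerate

    def test_same_seed_same_rewiring(self, rng):
        a = (rng.uniform(size=(22, 22)) < 0.3).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        net = _net(a)
        n1 = rewire_preserving_degree(net, seed=42)
        n2 = rewire_preserving_degree(net, seed=42)
        assert np.array_equal(n1.adjacency, n2.adjacency)


class TestSmallWorld:
    def test_self_null_consistency(self):
        g = nx.watts_strogatz_graph(22, 6, 0.1, seed=1)
        net = BinaryNetwork.from_networkx(g, 22, 0.0, "absolute_r")
        sw = small_worldness(net, n_null=50, seed=3)
        # a network drawn from the null family has gamma ~ 1 on average
        gammas = [small_worldness(rewire_preserving_degree(net, seed=9 + k),
                                  n_null=50, seed=5 + k).gamma
                  for k in range(10)]
        assert np.mean(gammas) == pytest.approx(1.0, abs=0.15)
        assert sw.gamma > np.mean(gammas)  # lattice-like structure inflates clustering

    def test_watts_strogatz_is_small_world(self):
        g = nx.watts_strogatz_graph(22, 6, 0.1, seed=7)
        net = BinaryNetwork.from_networkx(g, 22, 0.0, "absolute_r")
        sw = small_worldness(net, n_null=100, seed=11)
        assert sw.sigma > 1.0
        assert sw.gamma > 1.0


class TestSweepAndNodal:
    def test_eglobal_nondecreasing_and_auc_of_constant(self, rng):
        v = rng.uniform(0, 1, size=(22, 22))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        prof = metric_sweep(ConnectivityMatrix(v))
        assert np.all(np.diff(prof.eglobal) >= -1e-12)
        const = GraphMetricProfile(
            thresholds=prof.thresholds, cnet=np.full(9, 0.37),
            eglobal=np.zeros(9), eloc=np.zeros(9), lp=np.zeros(9),
            nodal_bc=np.zeros((9, 22)), nodal_eloc=np.zeros((9, 22)))
        assert const.auc("cnet") == pytest.approx(0.37)

    def test_identical_profiles_give_null_tests(self, rng):
        v = rng.uniform(0, 1, size=(22, 22))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        profs = [metric_sweep(ConnectivityMatrix(v)) for _ in range(4)]
        for metric in ("betweenness", "nodal_eloc"):
            df = nodal_group_comparison(profs, profs, metric)
            assert len(df) == 22
            assert list(df.channel) == [f"CH{i:02d}" for i in range(1, 23)]
            assert np.allclose(df.t, 0.0)
            assert np.allclose(df.p, 1.0)
            assert not df.significant.any()
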