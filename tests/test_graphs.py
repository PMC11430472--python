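"""Binarization, graph metrics, Newman modularity, and the 74-feature block."""

import itertools

import networkx as nx
import numpy as np
import pytest

import connstates as cs
from conftest import random_connectivity


def graph_from_edges(n, edges):
    A = np.zeros((n, n))
    for i, j in edges:
        A[i, j] = A[j, i] = 1.0
    return cs.BinaryGraph(adjacency=A, density=1.0, scope="whole_brain")


class TestBinarizeAtDensity:
    def test_paper_scale_edge_count(self, rng):
        M = rng.standard_normal((400, 400))
        M = (M + M.T) / 2
        g = cs.binarize_at_density(M, 0.10)
        assert g.n_edges == 7980  # round(0.10 * 400*399/2)

    def test_density_one_gives_complete_graph(self, rng):
        M = rng.standard_normal((10, 10))
        M = (M + M.T) / 2
        g = cs.binarize_at_density(M, 1.0)
        assert g.n_edges == 45

    def test_retained_set_is_top_k_by_value(self, rng):
        M = rng.standard_normal((15, 15))
        M = (M + M.T) / 2
        g = cs.binarize_at_density(M, 0.2)
        iu, ju = np.triu_indices(15, k=1)
        vals = M[iu, ju]
        k = g.n_edges
        kept = g.adjacency[iu, ju] > 0
        assert set(np.round(vals[kept], 12)) == set(np.round(np.sort(vals)[-k:], 12))

    def test_zero_edges_is_an_error(self):
        M = np.eye(4)
        with pytest.raises(ValueError, match="0 edges"):
            cs.binarize_at_density(M, 0.01)


class TestShortestPaths:
    def test_path_graph(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        D = cs.shortest_paths(g)
        assert D[0, 2] == 2

    def test_complete_k4(self):
        g = graph_from_edges(4, itertools.combinations(range(4), 2))
        D = cs.shortest_paths(g)
        off = ~np.eye(4, dtype=bool)
        assert np.all(D[off] == 1)

    def test_disconnected_inverse_distance_zero(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        inv = cs.inverse_distance(g)
        assert inv[0, 2] == 0.0 and inv[1, 3] == 0.0


class TestNodeMetrics:
    def test_path3_global_efficiency(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        assert cs.global_efficiency(g) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_triangle_and_star_clustering(self):
        tri = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert np.allclose(cs.clustering_coefficients(tri), 1.0)
        star = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert np.allclose(cs.clustering_coefficients(star), 0.0)

    def test_k4_minus_edge_clustering(self):
        edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]  # K4 minus (2,3)
        C = cs.clustering_coefficients(graph_from_edges(4, edges))
        assert np.allclose(np.sort(C), [2 / 3, 2 / 3, 1, 1])
        assert C.mean() == pytest.approx(5 / 6)

    def test_participation_formula_cases(self):
        # node 0: two edges in community A, two in community B -> 1 - 2*(1/2)^2
        g = graph_from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (3, 4)])
        comm = cs.CommunityAssignment(labels=np.array([0, 0, 0, 1, 1]), Q=0.0)
        part = cs.participation_coefficients(g, comm)
        assert part[0] == pytest.approx(0.5)
        # all of node 1's edges inside its own community -> 0
        assert part[1] == pytest.approx(0.0)

    def test_isolated_node_participation_zero(self):
        g = graph_from_edges(3, [(0, 1)])
        comm = cs.CommunityAssignment(labels=np.array([0, 0, 1]), Q=0.0)
        assert cs.participation_coefficients(g, comm)[2] == 0.0


def brute_force_best_partition(A):
    """Maximum modularity over ALL partitions (Bell-number enumeration)."""
    n = A.shape[0]

    def partitions(nodes):
        if not nodes:
            yield []
            return
        first, rest = nodes[0], nodes[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part

    best = -np.inf
    for part in partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, group in enumerate(part):
            labels[group] = c
        q = cs.modularity_value(A, labels)
        best = max(best, q)
    return best


class TestNewmanModularity:
    def test_two_disconnected_triangles(self):
        A = graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]).adjacency
        comm = cs.newman_modularity(A)
        assert comm.Q == pytest.approx(0.5)
        assert comm.n_communities == 2
        assert len(set(comm.labels[:3])) == 1 and len(set(comm.labels[3:])) == 1

    def test_complete_graph_single_community(self):
        A = graph_from_edges(5, itertools.combinations(range(5), 2)).adjacency
        comm = cs.newman_modularity(A)
        assert comm.n_communities == 1
        assert comm.Q == pytest.approx(0.0)

    def test_two_cliques_with_bridge_attains_brute_force_optimum(self):
        edges = list(itertools.combinations(range(4), 2))
        edges += [(i + 4, j + 4) for i, j in itertools.combinations(range(4), 2)]
        edges += [(3, 4)]
        A = graph_from_edges(8, edges).adjacency
        comm = cs.newman_modularity(A)
        assert comm.Q == pytest.approx(brute_force_best_partition(A), abs=1e-9)
        assert len(set(comm.labels[:4])) == 1 and len(set(comm.labels[4:])) == 1
        assert comm.labels[0] != comm.labels[7]

    def test_q_matches_formula_on_returned_labels(self, rng):
        M = rng.standard_normal((30, 30))
        M = (M + M.T) / 2
        A = cs.binarize_at_density(M, 0.2).adjacency
        comm = cs.newman_modularity(A)
        assert comm.Q == pytest.approx(cs.modularity_value(A, comm.labels), abs=1e-10)

    def test_edgeless_graph_is_an_error(self):
        with pytest.raises(cs.EdgelessGraphError):
            cs.newman_modularity(np.zeros((4, 4)))

    def test_deterministic(self, rng):
        M = rng.standard_normal((40, 40))
        M = (M + M.T) / 2
        A = cs.binarize_at_density(M, 0.15).adjacency
        a = cs.newman_modularity(A)
        b = cs.newman_modularity(A)
        assert np.array_equal(a.labels, b.labels) and a.Q == b.Q


class TestGraphFeatureBlock:
    def test_emits_74_named_features(self, part21):
        cm = random_connectivity(21, seed=3)
        block = cs.graph_feature_block(cm, part21, density=0.3)
        assert len(block) == 74
        assert sum(":eff:" in n or ":intra_eff:" in n for n in block.names) == 36
        assert sum(":clust:" in n or ":intra_clust:" in n for n in block.names) == 15
        assert sum(":modularity:" in n for n in block.names) == 8
        assert sum(":part:" in n or ":intra_part:" in n for n in block.names) == 15

    def test_gsr_and_nogsr_blocks_are_independent(self, part21):
        a = cs.graph_feature_block(random_connectivity(21, 3, "noGSR"), part21, density=0.3)
        b = cs.graph_feature_block(random_connectivity(21, 4, "GSR"), part21, density=0.3)
        assert a.family == "graph_noGSR" and b.family == "graph_GSR"
        assert not np.allclose(a.values, b.values)

    def test_permutation_invariance(self, part21, rng):
        cm = random_connectivity(21, seed=6)
        block = cs.graph_feature_block(cm, part21, density=0.3)
        perm = rng.permutation(21)
        perm_part = cs.NetworkPartition(
            labels=tuple(part21.labels[i] for i in perm), networks=part21.networks)
        perm_cm = cs.ConnectivityMatrix(cm.values[np.ix_(perm, perm)], cm.variant)
        perm_block = cs.graph_feature_block(perm_cm, perm_part, density=0.3)
        assert np.allclose(perm_block.values, block.values, atol=1e-10)

    def test_whole_brain_complete_graph_efficiencies_are_one(self, part21):
        v = np.linspace(0.5, 0.9, 21 * 21).reshape(21, 21)
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        cm = cs.ConnectivityMatrix(np.clip(v, -1, 1), "GSR")
        block = cs.efficiency_features(cm, part21, density=1.0).as_series()
        whole_level = [n for n in block.index if ":eff:" in n]
        assert np.allclose(block[whole_level], 1.0)


class TestMetricsAgainstNetworkx:
    """Independent oracle: networkx on random binarized graphs."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_efficiency_and_clustering(self, seed, rng):
        M = np.random.default_rng(seed).standard_normal((25, 25))
        M = (M + M.T) / 2
        g = cs.binarize_at_density(M, 0.15)
        G = nx.from_numpy_array(g.adjacency)
        assert cs.global_efficiency(g) == pytest.approx(nx.global_efficiency(G), abs=1e-12)
        C = cs.clustering_coefficients(g)
        C_nx = np.array([nx.clustering(G, i) for i in range(25)])
        assert np.allclose(C, C_nx, atol=1e-12)
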