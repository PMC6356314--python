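"""Edge weighting, kernels, cross-diffusion, hierarchical fusion."""

import networkx as nx
import numpy as np
import pytest

from fdp.network_fusion import (
    ActiveNetwork,
    align_active_networks,
    diffuse_pair,
    edge_clustering_coefficient,
    edge_weight,
    full_kernel,
    fuse_all,
    fuse_pair,
    knn_kernel,
    network_distance,
    weight_matrix,
)


def brute_force_ecc(graph, u, v):
    """Independent oracle: explicit set intersection and min-degree count."""
    common = sum(1 for w in graph.nodes if graph.has_edge(u, w) and graph.has_edge(v, w))
    denom = min(graph.degree(u) - 1, graph.degree(v) - 1)
    return common / denom if denom > 0 else 0.0


class TestEdgeClusteringCoefficient:
    def test_triangle_edge(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert edge_clustering_coefficient(g, "a", "b") == 1.0

    def test_path_edge_has_no_triangles(self):
        g = nx.path_graph(["a", "b", "c"])
        assert edge_clustering_coefficient(g, "a", "b") == 0.0

    def test_non_edge_rejected(self):
        g = nx.path_graph(["a", "b", "c"])
        with pytest.raises(ValueError):
            edge_clustering_coefficient(g, "a", "c")

    def test_matches_oracle_on_random_graphs(self, rng):
        for trial in range(30):
            g = nx.gnp_random_graph(12, 0.4, seed=int(rng.integers(2**31)))
            for u, v in g.edges:
                assert edge_clustering_coefficient(g, u, v) == brute_force_ecc(g, u, v)


class TestEdgeWeight:
    def test_triangle_weight_is_e_squared(self):
        g = nx.complete_graph(["a", "b", "c"])
        assert edge_weight(g, "a", "b") == pytest.approx(np.e**2, rel=1e-12)

    def test_clique_weight_is_e_squared(self):
        g = nx.complete_graph(4)
        assert edge_weight(g, 0, 1) == pytest.approx(np.e**2, rel=1e-12)

    def test_no_clustering_gives_neutral_weight(self):
        g = nx.path_graph(["a", "b", "c"])
        assert edge_weight(g, "a", "b") == 1.0

    def test_weight_matrix_agrees_with_per_edge(self, rng):
        g = nx.relabel_nodes(
            nx.gnp_random_graph(10, 0.5, seed=7), {n: f"n{n}" for n in range(10)}
        )
        nodes = sorted(g.nodes)
        W = weight_matrix(g, nodes)
        for u, v in g.edges:
            i, j = nodes.index(u), nodes.index(v)
            assert W[i, j] == pytest.approx(edge_weight(g, u, v), rel=1e-12)
        assert np.array_equal(W, W.T)
        assert np.all(np.diag(W) == 0.0)


class TestKernels:
    def test_star_full_kernel_row(self):
        g = nx.star_graph(["c", "x", "y", "z"])
        W = np.zeros((4, 4))
        order = ["c", "x", "y", "z"]
        for leaf in "xyz":
            i, j = order.index("c"), order.index(leaf)
            W[i, j] = W[j, i] = 1.0
        P = full_kernel(W)
        assert P[0, 0] == 0.5
        assert np.allclose(P[0, 1:], 1 / 6)

    def test_isolated_row_is_unit_diagonal(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 2.0
        P = full_kernel(W)
        assert list(P[2]) == [0.0, 0.0, 1.0]
        S = knn_kernel(W, K=5)
        assert list(S[2]) == [0.0, 0.0, 1.0]

    def test_row_sums(self, rng):
        W = rng.uniform(0, 2, (15, 15)) * (rng.random((15, 15)) < 0.4)
        W = np.triu(W, 1)
        W = W + W.T
        P = full_kernel(W)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        S = knn_kernel(W, K=4)
        connected = W.sum(axis=1) > 0
        assert np.allclose(S[connected].sum(axis=1), 0.5, atol=1e-12)

    def test_knn_keeps_fewer_than_K_neighbors(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        W[0, 2] = W[2, 0] = 2.0
        S = knn_kernel(W, K=20)
        assert S[0, 1] == pytest.approx(1 / 6)
        assert S[0, 2] == pytest.approx(2 / 6)

    def test_knn_tie_break_keeps_lowest_indices(self):
        n = 26
        W = np.zeros((n, n))
        W[0, 1:] = W[1:, 0] = 1.0  # 25 equal-weight neighbors
        S = knn_kernel(W, K=20)
        kept = np.flatnonzero(S[0])
        assert list(kept) == list(range(1, 21))

    def test_knn_support_matches_sorted_oracle(self, rng):
        W = rng.uniform(0, 1, (12, 12)) * (rng.random((12, 12)) < 0.6)
        W = np.triu(W, 1)
        W = W + W.T
        S = knn_kernel(W, K=3)
        for i in range(12):
            nbrs = np.flatnonzero(W[i])
            if nbrs.size == 0:
                continue
            top3 = sorted(nbrs, key=lambda j: (-W[i, j], j))[:3]
            assert set(np.flatnonzero(S[i])) == set(top3)

    def test_knn_rejects_bad_K(self):
        with pytest.raises(ValueError):
            knn_kernel(np.zeros((2, 2)), K=0)


class TestNetworkDistance:
    def test_zero_for_identical(self, rng):
        W = rng.random((5, 5))
        assert network_distance(W, W) == 0.0

    def test_single_pair_closed_form(self):
        Wa = np.zeros((4, 4))
        Wb = np.zeros((4, 4))
        Wb[1, 2] = Wb[2, 1] = 3.0
        assert network_distance(Wa, Wb) == pytest.approx(np.sqrt(18.0))

    def test_matches_entrywise_oracle(self, rng):
        Wa, Wb = rng.random((6, 6)), rng.random((6, 6))
        oracle = np.sqrt(((Wa - Wb) ** 2).sum())
        assert network_distance(Wa, Wb) == pytest.approx(oracle, rel=1e-14)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            network_distance(np.zeros((3, 3)), np.zeros((4, 4)))


class TestDiffusion:
    def test_identity_kernel_swaps_and_scales(self, rng):
        Pa, Pb = rng.random((4, 4)), rng.random((4, 4))
        Sa = Sb = 0.5 * np.eye(4)
        Pa1, Pb1 = diffuse_pair(Pa, Pb, Sa, Sb, t_max=1)
        assert np.allclose(Pa1, Pb / 4.0)
        assert np.allclose(Pb1, Pa / 4.0)

    def test_equal_inputs_stay_equal(self, rng):
        P = rng.random((5, 5))
        S = rng.random((5, 5))
        Pa_t, Pb_t = diffuse_pair(P, P, S, S, t_max=7)
        assert np.array_equal(Pa_t, Pb_t)

    def test_matches_loop_oracle(self, rng):
        Pa, Pb = rng.random((6, 6)), rng.random((6, 6))
        Sa, Sb = rng.random((6, 6)), rng.random((6, 6))
        Qa, Qb = Pa.copy(), Pb.copy()
        for _ in range(3):  # hand-rolled simultaneous update
            Qa, Qb = Sa @ Qb @ Sa.T, Sb @ Qa @ Sb.T
        Pa_t, Pb_t = diffuse_pair(Pa, Pb, Sa, Sb, t_max=3)
        assert np.allclose(Pa_t, Qa, atol=1e-12)
        assert np.allclose(Pb_t, Qb, atol=1e-12)

    def test_nonnegativity_preserved(self, rng):
        W = rng.uniform(0, 1, (8, 8))
        W = np.triu(W, 1) + np.triu(W, 1).T
        Pa_t, Pb_t = diffuse_pair(
            full_kernel(W), full_kernel(W), knn_kernel(W, 3), knn_kernel(W, 3), 20
        )
        assert np.all(Pa_t >= 0) and np.all(Pb_t >= 0)

    def test_fuse_pair_is_elementwise_mean(self, rng):
        A, B = rng.random((4, 4)), rng.random((4, 4))
        assert np.allclose(fuse_pair(A, B), (A + B) / 2)
        assert np.allclose(fuse_pair(np.zeros((2, 2)), np.ones((2, 2))), 0.5)


def _aligned(graphs):
    return align_active_networks(graphs)


class TestFuseAll:
    def test_single_network_returns_its_full_kernel(self):
        g = nx.complete_graph(["a", "b", "c"])
        nets = _aligned([g])
        fused = fuse_all(nets)
        assert np.allclose(fused.R, full_kernel(nets[0].W))
        assert fused.fusion_order == ()

    def test_two_identical_networks_symmetric_in_order(self):
        g = nx.complete_graph(["a", "b", "c", "d"])
        fused_ab = fuse_all(_aligned([g, g.copy()]), K=3)
        fused_ba = fuse_all(list(reversed(_aligned([g, g.copy()]))), K=3)
        assert np.allclose(fused_ab.R, fused_ba.R)

    def test_closest_pair_merges_first(self):
        g1 = nx.complete_graph(["a", "b", "c"])
        g3 = nx.Graph([("a", "b")])
        fused = fuse_all(_aligned([g1, g1.copy(), g3]), K=3)
        assert fused.fusion_order[0] == ("t1", "t2")

    def test_fusion_order_stable_under_permutation(self):
        g1 = nx.complete_graph(["a", "b", "c"])
        g2 = nx.Graph([("a", "b"), ("b", "c")])
        g3 = nx.Graph([("a", "c")])
        nets = _aligned([g1, g2, g3])
        order1 = fuse_all(nets, K=3).fusion_order
        order2 = fuse_all([nets[2], nets[0], nets[1]], K=3).fusion_order
        assert order1 == order2

    def test_empty_networks_skipped_and_all_empty_raises(self):
        g = nx.complete_graph(["a", "b", "c"])
        empty = nx.Graph()
        empty.add_nodes_from("abc")
        nets = _aligned([g, empty])
        fused = fuse_all(nets)
        assert np.allclose(fused.R, full_kernel(nets[0].W))
        with pytest.raises(ValueError, match="empty"):
            fuse_all(_aligned([empty, empty.copy()]))

    def test_deterministic_bit_identical(self, small_fixture, small_profiles):
        from fdp.expression_dynamics import build_active_networks, classify_profiles

        classes = classify_profiles(small_profiles.values())
        graphs = build_active_networks(
            small_fixture.network, small_profiles, classes
        )
        r1 = fuse_all(align_active_networks(graphs), K=5)
        r2 = fuse_all(align_active_networks(graphs), K=5)
        assert np.array_equal(r1.R, r2.R)
        assert r1.fusion_order == r2.fusion_order
        assert np.all(r1.R >= 0) and np.all(np.isfinite(r1.R))
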