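import numpy as np
import networkx as nx
import pytest

from ctnetwb.topology import (
    NODE_METRICS,
    betweenness_centrality,
    compute_all_metrics,
    degree_centrality,
    eigenvector_centrality,
    global_efficiency,
    local_efficiency,
    nodal_efficiency,
    pagerank_centrality,
    shortest_paths,
)

from . import oracles


def adjacency(graph: nx.Graph) -> np.ndarray:
    return nx.to_numpy_array(graph, dtype=int)


P3 = adjacency(nx.path_graph(3))
K4 = adjacency(nx.complete_graph(4))
STAR4 = adjacency(nx.star_graph(3))  # centre 0 + 3 leaves
C5 = adjacency(nx.cycle_graph(5))


class TestShortestPaths:
    def test_chain_and_clique_distances(self):
        assert shortest_paths(P3).lengths[0, 2] == 2
        L = shortest_paths(K4).lengths
        assert (L[~np.eye(4, dtype=bool)] == 1).all()

    def test_distances_and_counts_match_oracle(self, rng):
        for _ in range(25):
            A = oracles.connected_random_graph(rng, 8)
            sp = shortest_paths(A)
            np.testing.assert_array_equal(sp.lengths, oracles.floyd_warshall(A))
            for s in range(8):
                for t in range(8):
                    if s != t:
                        assert sp.counts[s, t] == len(oracles.all_shortest_paths(A, s, t))

    def test_unreachable_pairs_infinite(self):
        A = np.zeros((4, 4), dtype=int)
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1
        sp = shortest_paths(A)
        assert np.isinf(sp.lengths[0, 2])


class TestClosedForms:
    def test_global_efficiency(self):
        assert global_efficiency(K4) == pytest.approx(1.0)
        assert global_efficiency(P3) == pytest.approx(5 / 6)
        two_pairs = np.zeros((4, 4), dtype=int)
        two_pairs[0, 1] = two_pairs[1, 0] = two_pairs[2, 3] = two_pairs[3, 2] = 1
        assert global_efficiency(two_pairs) == pytest.approx(1 / 3)

    def test_nodal_efficiency(self):
        assert nodal_efficiency(shortest_paths(STAR4), 0) == pytest.approx(1.0)
        assert nodal_efficiency(shortest_paths(P3), 0) == pytest.approx(3 / 4)
        isolated = np.zeros((3, 3), dtype=int)
        isolated[1, 2] = isolated[2, 1] = 1
        assert nodal_efficiency(shortest_paths(isolated), 0) == 0.0

    def test_local_efficiency(self):
        K3 = adjacency(nx.complete_graph(3))
        assert local_efficiency(K3, 0) == pytest.approx(1.0)
        assert local_efficiency(STAR4, 0) == 0.0  # leaves mutually non-adjacent
        assert local_efficiency(P3, 0) == 0.0  # degree-1 convention

    def test_degree_and_handshake(self, rng):
        assert degree_centrality(K4, 2) == 3
        A = oracles.connected_random_graph(rng, 8)
        total = sum(degree_centrality(A, i) for i in range(8))
        assert total == A.sum() == 2 * (A.sum() // 2)

    def test_betweenness_ordered_pairs(self):
        # centre of a 3-path carries both ordered pairs (0,2) and (2,0)
        assert betweenness_centrality(shortest_paths(P3), 1) == pytest.approx(2.0)
        for i in range(4):
            assert betweenness_centrality(shortest_paths(K4), i) == 0.0

    def test_eigenvector_uniform_on_complete_graph(self):
        v, pair = eigenvector_centrality(K4)
        np.testing.assert_allclose(v, 0.5)
        assert pair.lambda_1 == pytest.approx(3.0)
        residual = K4 @ v - pair.lambda_1 * v
        assert np.max(np.abs(residual)) < 1e-10

    def test_eigenvector_star_centre_dominates(self):
        v, _ = eigenvector_centrality(STAR4)
        assert v[0] > v[1:].max()
        np.testing.assert_allclose(v, oracles.eigenvector_centrality(STAR4), atol=1e-10)

    def test_pagerank_uniform_on_regular_graphs(self):
        np.testing.assert_allclose(pagerank_centrality(C5), 1.0, atol=1e-12)
        np.testing.assert_allclose(pagerank_centrality(K4), 1.0, atol=1e-12)

    def test_pagerank_star_and_residual(self, rng):
        r = pagerank_centrality(STAR4)
        assert r[0] > r[1]
        assert r.sum() == pytest.approx(4.0)
        A = oracles.connected_random_graph(rng, 8)
        np.testing.assert_allclose(
            pagerank_centrality(A), oracles.pagerank(A), atol=1e-10
        )


class TestOracleEquivalence:
    def test_all_metrics_match_brute_force_on_random_graphs(self, rng):
        for _ in range(20):
            A = oracles.connected_random_graph(rng, 8)
            sp = shortest_paths(A)
            assert global_efficiency(sp) == pytest.approx(
                oracles.global_efficiency(A), abs=1e-9
            )
            for i in range(8):
                assert nodal_efficiency(sp, i) == pytest.approx(
                    oracles.nodal_efficiency(A, i), abs=1e-9
                )
                assert local_efficiency(A, i) == pytest.approx(
                    oracles.local_efficiency(A, i), abs=1e-9
                )
                assert betweenness_centrality(sp, i) == pytest.approx(
                    oracles.betweenness(A, i), abs=1e-9
                )

    def test_betweenness_is_twice_networkx_convention(self, rng):
        A = oracles.connected_random_graph(rng, 8)
        G = nx.from_numpy_array(A)
        nx_bc = nx.betweenness_centrality(G, normalized=False)
        sp = shortest_paths(A)
        for i in range(8):
            assert betweenness_centrality(sp, i) == pytest.approx(2 * nx_bc[i], abs=1e-9)


class TestInvariants:
    def test_eglob_is_mean_enodal(self, rng):
        A = oracles.connected_random_graph(rng, 8)
        sp = shortest_paths(A)
        enodal = [nodal_efficiency(sp, i) for i in range(8)]
        assert global_efficiency(sp) == pytest.approx(np.mean(enodal))

    def test_adding_edge_never_decreases_eglob(self, rng):
        for _ in range(10):
            A = oracles.connected_random_graph(rng, 7)
            e0 = global_efficiency(A)
            empty = np.argwhere(np.triu(A == 0, 1))
            if len(empty) == 0:
                continue
            i, j = empty[rng.integers(len(empty))]
            B = A.copy()
            B[i, j] = B[j, i] = 1
            assert global_efficiency(B) >= e0 - 1e-12

    def test_permutation_equivariance_of_all_metrics(self, rng):
        A = oracles.connected_random_graph(rng, 8)
        perm = rng.permutation(8)
        B = A[np.ix_(perm, perm)]
        ta = compute_all_metrics(A).node_table.pivot(
            index="parcel", columns="metric", values="value"
        )
        tb = compute_all_metrics(B).node_table.pivot(
            index="parcel", columns="metric", values="value"
        )
        for new_idx, old_idx in enumerate(perm):
            for metric in NODE_METRICS:
                assert tb.loc[f"node_{new_idx}", metric] == pytest.approx(
                    ta.loc[f"node_{old_idx}", metric], abs=1e-9
                )


class TestComputeAllMetrics:
    def test_path_graph_table(self):
        result = compute_all_metrics(P3)
        t = result.node_table.pivot(index="parcel", columns="metric", values="value")
        assert result.eglob == pytest.approx(5 / 6)
        assert t.loc["node_1", "BC"] == pytest.approx(2.0)
        assert t.loc["node_1", "DC"] == 2
        assert t.loc["node_0", "Elocal"] == 0.0
        assert t.loc["node_1", "Enodal"] == pytest.approx(1.0)

    def test_cohort_shape_contract(self, small_cohort):
        from ctnetwb.pipeline import compute_network_metrics

        metrics, eglob = compute_network_metrics(
            small_cohort.thickness, small_cohort.parcel_table
        )
        n, p = 10, 8
        assert len(metrics) == n * p * 6
        assert len(eglob) == n
        assert set(metrics["metric"]) == set(NODE_METRICS)
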