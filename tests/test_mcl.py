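import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from ichd_matrix import (
    BiadjacencyMatrix,
    MCLParams,
    bipartite_to_adjacency,
    mcl,
    modularity,
    sweep,
)
from oracles import modularity_by_edge_counting, naive_mcl


def labelled(n):
    return tuple(f"n{i}" for i in range(n))


def two_triangles():
    adj = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        adj[a, b] = adj[b, a] = 1
    return adj


class TestAdjacency:
    def test_single_cell_matrix_is_single_edge(self):
        m = BiadjacencyMatrix(("r",), ("c",), np.array([[1]]))
        labels, adj = bipartite_to_adjacency(m)
        assert labels == ("p:r", "c:c")
        assert adj.tolist() == [[0, 1], [1, 0]]

    def test_ndph_matrix_is_a_star(self, ndph_criteria):
        from ichd_matrix import build_matrix

        labels, adj = bipartite_to_adjacency(build_matrix(ndph_criteria))
        assert adj.shape == (5, 5)
        degrees = adj.sum(axis=1)
        assert sorted(degrees.tolist()) == [1, 1, 1, 1, 4]

    def test_same_axis_blocks_are_zero(self, reference_matrix):
        n_rows = reference_matrix.shape[0]
        _, adj = bipartite_to_adjacency(reference_matrix)
        assert not adj[:n_rows, :n_rows].any()
        assert not adj[n_rows:, n_rows:].any()


class TestMcl:
    def test_disjoint_triangles_stay_separate(self):
        clustering = mcl(two_triangles(), labelled(6), MCLParams())
        assert {frozenset({"n0", "n1", "n2"}), frozenset({"n3", "n4", "n5"})} == set(
            clustering.clusters
        )

    def test_star_collapses_to_one_cluster(self, ndph_criteria):
        from ichd_matrix import build_matrix

        labels, adj = bipartite_to_adjacency(build_matrix(ndph_criteria))
        clustering = mcl(adj, labels, MCLParams())
        assert clustering.n_clusters == 1
        assert clustering.clusters[0] == frozenset(labels)

    @pytest.mark.parametrize("inflation", [1.6, 2.0, 3.0])
    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_matches_naive_reference_on_small_graphs(self, inflation, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 25))
        adj = (rng.random((n, n)) < 0.2).astype(float)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        params = MCLParams(inflation=inflation)
        ours = mcl(adj, labelled(n), params)
        index = {l: i for i, l in enumerate(labelled(n))}
        ours_idx = {frozenset(index[l] for l in c) for c in ours.clusters}
        reference = naive_mcl(adj.tolist(), inflation=inflation)
        assert ours_idx == reference

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_disconnected_components_never_merge(self, seed):
        rng = np.random.default_rng(seed)
        sizes = [int(rng.integers(2, 6)) for _ in range(3)]
        blocks = []
        for s in sizes:
            block = (rng.random((s, s)) < 0.8).astype(float)
            block = np.triu(block, 1)
            blocks.append(block + block.T)
        adj = np.zeros((sum(sizes), sum(sizes)))
        offset = 0
        component = {}
        for k, block in enumerate(blocks):
            s = block.shape[0]
            adj[offset : offset + s, offset : offset + s] = block
            for i in range(s):
                component[f"n{offset + i}"] = k
            offset += s
        clustering = mcl(adj, labelled(adj.shape[0]), MCLParams())
        for cluster in clustering.clusters:
            assert len({component[node] for node in cluster}) == 1

    def test_node_relabeling_permutes_clusters(self):
        adj = two_triangles()
        base = {frozenset(c) for c in mcl(adj, labelled(6), MCLParams()).clusters}
        perm = [3, 4, 5, 0, 1, 2]
        padj = adj[np.ix_(perm, perm)]
        plabels = tuple(f"n{perm[i]}" for i in range(6))
        permuted = {frozenset(c) for c in mcl(padj, plabels, MCLParams()).clusters}
        assert permuted == base

    def test_every_node_is_covered(self, reference_matrix):
        labels, adj = bipartite_to_adjacency(reference_matrix)
        clustering = mcl(adj, labels, MCLParams(expansion=3, inflation=3.3))
        covered = set().union(*clustering.clusters)
        assert covered == set(labels)

    def test_rejects_asymmetric_input(self):
        with pytest.raises(ValueError, match="symmetric"):
            mcl(np.array([[0.0, 1.0], [0.0, 0.0]]), labelled(2), MCLParams())


class TestModularity:
    def test_two_triangles_closed_form(self):
        # L_c=3, d_c=6, m=6 per component: Q = 2*(3/6 - (6/12)^2) = 0.5
        membership = {f"n{i}": i // 3 for i in range(6)}
        assert modularity(two_triangles(), membership, labelled(6)) == pytest.approx(0.5)

    def test_single_cluster_is_zero(self):
        membership = {f"n{i}": 0 for i in range(6)}
        assert modularity(two_triangles(), membership, labelled(6)) == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_matches_edge_counting_oracle_and_networkx(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 15))
        adj = (rng.random((n, n)) < 0.4).astype(float)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        if not adj.any():
            return
        labels = labelled(n)
        membership = {l: int(rng.integers(0, 3)) for l in labels}
        edges = [
            (labels[i], labels[j]) for i in range(n) for j in range(i + 1, n) if adj[i, j]
        ]
        ours = modularity(adj, membership, labels)
        assert ours == pytest.approx(modularity_by_edge_counting(edges, membership))
        g = nx.Graph(edges)
        g.add_nodes_from(labels)
        communities = {}
        for node, c in membership.items():
            communities.setdefault(c, set()).add(node)
        assert ours == pytest.approx(
            nx.algorithms.community.modularity(g, communities.values())
        )

    def test_edgeless_graph_signals(self):
        with pytest.raises(ValueError, match="edgeless"):
            modularity(np.zeros((3, 3)), {f"n{i}": 0 for i in range(3)}, labelled(3))


class TestSweep:
    def test_single_value_grid_is_argmax(self):
        adj = two_triangles()
        result = sweep(adj, labelled(6), "inflation", [2.0], MCLParams())
        assert result.best == 2.0
        assert len(result.q_values) == 1

    def test_ties_break_to_smallest_value(self):
        # disconnected triangles cluster identically at any inflation
        adj = two_triangles()
        result = sweep(adj, labelled(6), "inflation", [2.0, 3.0], MCLParams())
        assert result.best == 2.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            sweep(two_triangles(), labelled(6), "inflation", [], MCLParams())

    def test_iterate_stays_column_stochastic(self, reference_matrix):
        sums_seen = []

        def record(_iteration, mat):
            sums_seen.append(mat.sum(axis=0))

        labels, adj = bipartite_to_adjacency(reference_matrix)
        mcl(adj, labels, MCLParams(expansion=3, inflation=3.3), iteration_callback=record)
        assert sums_seen
        for col_sums in sums_seen:
            np.testing.assert_allclose(col_sums, 1.0, atol=1e-9)
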