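"""Graph building, Markov clustering and the spectral k-means refinement."""

import networkx as nx
import numpy as np
import pytest

from synoverlap.errors import ParameterError, ValidationError
from synoverlap.ppi_network import (
    build_graph,
    kmeans_refine,
    mcl_cluster,
    select_clusters,
)


def reference_mcl(graph, inflation, expansion=2, self_loop=1.0,
                  prune=1e-5, max_iter=200, tol=1e-8):
    """Independent pure-Python MCL used as the oracle.

    Written with explicit list-of-lists matrix arithmetic (no numpy, no
    shared code with the implementation); clusters are the connected
    components of the attractor-support graph of the limit matrix.
    """
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    size = len(nodes)
    m = [[0.0] * size for _ in range(size)]
    for a, b, data in graph.edges(data=True):
        w = data.get("weight", 1.0)
        m[index[a]][index[b]] = w
        m[index[b]][index[a]] = w
    for i in range(size):
        m[i][i] += self_loop
    def normalize(mat):
        for j in range(size):
            s = sum(mat[i][j] for i in range(size)) or 1.0
            for i in range(size):
                mat[i][j] /= s
    normalize(m)
    for _ in range(max_iter):
        sq = [[sum(m[i][x] * m[x][j] for x in range(size)) for j in range(size)]
              for i in range(size)]
        if expansion > 2:
            for _ in range(expansion - 2):
                sq = [[sum(sq[i][x] * m[x][j] for x in range(size))
                       for j in range(size)] for i in range(size)]
        new = [[(v ** inflation if v >= prune else 0.0) for v in row] for row in sq]
        normalize(new)
        delta = max(abs(new[i][j] - m[i][j]) for i in range(size) for j in range(size))
        m = new
        if delta < tol:
            break
    support = nx.Graph()
    support.add_nodes_from(range(size))
    for i in range(size):
        for j in range(size):
            if m[i][j] > 1e-9:
                support.add_edge(i, j)
    return [frozenset(nodes[i] for i in comp) for comp in nx.connected_components(support)]


def as_sets(partition):
    return {frozenset(c) for c in partition.clusters}


class TestBuildGraph:
    def test_threshold_boundary_inclusive(self):
        graph = build_graph([("a", "b", 0.39), ("a", "c", 0.40)])
        assert not graph.graph.has_edge("a", "b")
        assert graph.graph.has_edge("a", "c")

    def test_string_scale_autodetected(self):
        graph = build_graph([("a", "b", 400), ("b", "c", 700)])
        assert graph.score_scale == "0-1000"
        assert graph.graph["a"]["b"]["weight"] == pytest.approx(0.4)
        assert graph.graph["b"]["c"]["weight"] == pytest.approx(0.7)

    def test_duplicate_pairs_keep_max_score(self):
        graph = build_graph([("a", "b", 0.5), ("b", "a", 0.8)])
        assert graph.graph["a"]["b"]["weight"] == pytest.approx(0.8)
        assert graph.n_edges() == 1

    def test_universe_members_without_edges_reported_isolated(self):
        universe = {f"p{i}" for i in range(10)}
        edges = [(f"p{i}", f"p{i+1}", 0.9) for i in range(6)]
        graph = build_graph(edges, node_universe=universe)
        assert graph.n_nodes() == 7
        assert set(graph.isolated) == {"p7", "p8", "p9"}

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValidationError):
            build_graph([("a", "b", -0.1)])
        with pytest.raises(ValidationError):
            build_graph([("a", "b", 1500)])


class TestMCL:
    def test_disconnected_triangles_split_into_components(self, two_triangles):
        partition = mcl_cluster(two_triangles, inflation=1.3)
        assert as_sets(partition) == {
            frozenset({"a0", "a1", "a2"}), frozenset({"b0", "b1", "b2"})}

    def test_bridged_cliques_split_at_the_bridge(self, bridged_cliques):
        partition = mcl_cluster(bridged_cliques, inflation=1.3)
        expected = {frozenset(reference_mcl(bridged_cliques, inflation=1.3)[0]),
                    frozenset(reference_mcl(bridged_cliques, inflation=1.3)[1])}
        assert as_sets(partition) == {
            frozenset({f"n{i}" for i in range(5)}),
            frozenset({f"n{i}" for i in range(5, 10)})}
        assert as_sets(partition) == expected

    def test_single_isolated_node_is_a_singleton_cluster(self):
        g = nx.Graph()
        g.add_node("lonely")
        partition = mcl_cluster(g, inflation=2.0)
        assert as_sets(partition) == {frozenset({"lonely"})}

    def test_matches_reference_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for trial in range(8):
            g = nx.gnp_random_graph(9, 0.35, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
            nx.set_edge_attributes(g, 1.0, "weight")
            if g.number_of_edges() == 0:
                continue
            ours = as_sets(mcl_cluster(g, inflation=2.0))
            ref = set(reference_mcl(g, inflation=2.0))
            assert ours == ref, f"trial {trial}"

    def test_inflation_must_exceed_one(self, two_triangles):
        with pytest.raises(ParameterError):
            mcl_cluster(two_triangles, inflation=1.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(ParameterError):
            mcl_cluster(nx.Graph(), inflation=2.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_never_merges_connected_components(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.Graph()
        for block in range(3):
            sub = nx.gnp_random_graph(5, 0.7, seed=seed * 3 + block)
            g = nx.union(g, nx.relabel_nodes(sub, {i: f"c{block}_{i}" for i in sub}))
        nx.set_edge_attributes(g, 1.0, "weight")
        components = list(nx.connected_components(g))
        partition = mcl_cluster(g, inflation=1.5)
        for cluster in partition.clusters:
            assert any(cluster <= comp for comp in components)

    @pytest.mark.parametrize("seed", range(4))
    def test_invariant_under_node_relabeling(self, seed):
        g = nx.gnp_random_graph(10, 0.4, seed=seed)
        nx.set_edge_attributes(g, 1.0, "weight")
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
        base = as_sets(mcl_cluster(g, inflation=2.0))
        rng = np.random.default_rng(seed)
        perm = dict(zip(sorted(g.nodes), rng.permutation(sorted(g.nodes))))
        relabeled = as_sets(mcl_cluster(nx.relabel_nodes(g, perm), inflation=2.0))
        assert {frozenset(perm[n] for n in c) for c in base} == relabeled

    def test_partition_axioms_hold(self, bridged_cliques):
        partition = mcl_cluster(bridged_cliques, inflation=1.6)
        nodes = [n for c in partition.clusters for n in c]
        assert len(nodes) == len(set(nodes)) == bridged_cliques.number_of_nodes()
        assert all(partition.clusters)


class TestKMeans:
    def test_components_recovered_when_k_matches(self, two_triangles):
        partition = kmeans_refine(two_triangles, k=2, seed=0)
        assert as_sets(partition) == {
            frozenset({"a0", "a1", "a2"}), frozenset({"b0", "b1", "b2"})}

    def test_k_one_groups_everything(self, two_triangles):
        partition = kmeans_refine(two_triangles, k=1, seed=0)
        assert as_sets(partition) == {frozenset(two_triangles.nodes)}

    def test_same_seed_same_partition(self, bridged_cliques):
        a = kmeans_refine(bridged_cliques, k=2, seed=17)
        b = kmeans_refine(bridged_cliques, k=2, seed=17)
        assert as_sets(a) == as_sets(b)

    def test_k_beyond_node_count_rejected(self, two_triangles):
        with pytest.raises(ParameterError):
            kmeans_refine(two_triangles, k=7, seed=0)


class TestSelectClusters:
    def _partition(self, sizes):
        from synoverlap.ppi_network import Partition

        clusters, start = [], 0
        for s in sizes:
            clusters.append({f"p{start + i:03d}" for i in range(s)})
            start += s
        return Partition(clusters=clusters, method="MCL", parameters={})

    def test_size_floor_mirrors_four_cluster_outcome(self):
        partition = self._partition([23, 13, 14, 16, 3, 1])
        kept = select_clusters(partition, min_size=4)
        assert [len(c) for c in kept] == [23, 16, 14, 13]

    def test_all_singletons_give_empty_list(self):
        assert select_clusters(self._partition([1, 1, 1]), min_size=4) == []

    def test_exactly_min_size_retained(self):
        kept = select_clusters(self._partition([4]), min_size=4)
        assert len(kept) == 1
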