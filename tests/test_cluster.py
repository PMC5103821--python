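"""Clustering algorithm tests, including an independent naive MCL oracle."""

import networkx as nx
import numpy as np
import pytest

from conftest import random_weighted_graph
from prox3c.cluster import (MCLParams, is_cover, is_partition, louvain_hard,
                            louvain_soft, mcl, membership_map, modularity,
                            oclustr)

SWEEP_INFLATIONS = [1.1, 1.325, 1.55, 1.775, 2.0]


def reference_mcl(graph: nx.Graph, inflation: float) -> list[frozenset]:
    """Independent naive MCL: dense fixed-point loop without pruning.

    Clusters are the attractor systems of the limit matrix (rows with
    non-zero diagonal, merged when their supports touch); the occasional
    node attracted to several systems is allocated to the lexicographically
    first cluster, the same deterministic convention the package uses.
    """
    nodes = sorted(graph.nodes, key=str)
    n = len(nodes)
    a = np.zeros((n, n))
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if graph.has_edge(u, v):
                a[i, j] = graph[u][v].get("weight", 1)
    a += np.eye(n)
    m = a / a.sum(axis=0)
    for _ in range(300):
        prev = m.copy()
        m = m @ m
        m = m ** inflation
        m /= m.sum(axis=0)
        if np.abs(m - prev).max() < 1e-8:
            break
    support = m > 1e-6
    attractors = [i for i in range(n) if support[i, i]]
    systems = nx.Graph()
    systems.add_nodes_from(attractors)
    for x in attractors:
        for y in attractors:
            if support[x, y] or support[y, x]:
                systems.add_edge(x, y)
    stars = []
    for comp in nx.connected_components(systems):
        members = set()
        for x in comp:
            members |= set(np.nonzero(support[x])[0])
        stars.append(members)
    out, seen = [], set()
    for c in sorted(stars, key=sorted):
        c = c - seen
        if c:
            out.append(frozenset(nodes[i] for i in c))
            seen |= set(c)
    for i in range(n):  # numerically orphaned nodes join their strongest column
        if i not in seen:
            out.append(frozenset({nodes[i]}))
    return out


class TestMCL:
    def test_disconnected_triangles(self, two_triangles_disjoint):
        clusters = mcl(two_triangles_disjoint)
        assert sorted(map(sorted, clusters)) == [["a", "b", "c"], ["d", "e", "f"]]

    def test_bridged_triangles_split_at_inflation_two(self, two_triangles_bridge):
        clusters = mcl(two_triangles_bridge, MCLParams(inflation=2.0))
        assert sorted(map(sorted, clusters)) == [["a", "b", "c"], ["d", "e", "f"]]

    def test_single_isolated_node(self):
        g = nx.Graph()
        g.add_node("x")
        assert mcl(g) == [{"x"}]

    def test_output_is_partition(self, two_triangles_bridge):
        for infl in SWEEP_INFLATIONS:
            clusters = mcl(two_triangles_bridge, MCLParams(inflation=infl))
            assert is_partition(clusters, two_triangles_bridge.nodes)

    @pytest.mark.parametrize("inflation", SWEEP_INFLATIONS)
    def test_agrees_with_reference_implementation(self, inflation):
        """Partition identity with an independently coded dense MCL on 20
        seeded random graphs of up to 30 nodes."""
        for seed in range(20):
            g = random_weighted_graph(10 + seed, p=0.25, seed=seed)
            ours = {frozenset(c) for c in mcl(g, MCLParams(inflation=inflation))}
            ref = set(reference_mcl(g, inflation))
            assert ours == ref, f"seed={seed}"


class TestLouvain:
    def test_bridged_triangles_partition_and_modularity(self, two_triangles_bridge):
        clusters, q = louvain_hard(two_triangles_bridge, seed=0)
        assert sorted(map(sorted, clusters)) == [["a", "b", "c"], ["d", "e", "f"]]
        assert q == pytest.approx(5 / 14)

    def test_complete_graph_single_cluster(self):
        k4 = nx.complete_graph(4)
        clusters, q = louvain_hard(k4, seed=1)
        assert clusters == [{0, 1, 2, 3}]
        assert q == pytest.approx(0.0)

    def test_deterministic_given_seed(self):
        g = random_weighted_graph(40, p=0.15, seed=5)
        assert louvain_hard(g, seed=7) == louvain_hard(g, seed=7)

    def test_isolated_nodes_become_singletons(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=2)
        g.add_node("z")
        clusters, _ = louvain_hard(g, seed=0)
        assert {"z"} in clusters


class TestLouvainSoft:
    def test_path_example(self):
        g = nx.path_graph(["a", "b", "c"])
        soft = louvain_soft(g, [{"a", "b"}, {"c"}])
        assert sorted(map(sorted, soft)) == [["a", "b", "c"], ["b", "c"]]

    def test_no_intercluster_edges_is_fixed_point(self, two_triangles_disjoint):
        hard = [{"a", "b", "c"}, {"d", "e", "f"}]
        assert louvain_soft(two_triangles_disjoint, hard) == [set(c) for c in hard]

    def test_soft_clusters_superset_of_hard(self):
        for seed in range(10):
            g = random_weighted_graph(25, p=0.2, seed=seed)
            hard, _ = louvain_hard(g, seed=seed)
            soft = louvain_soft(g, hard)
            for h, s in zip(hard, soft):
                assert h <= s

    def test_idempotent_with_respect_to_hard_input(self, two_triangles_bridge):
        hard, _ = louvain_hard(two_triangles_bridge, seed=0)
        assert louvain_soft(two_triangles_bridge, hard) == \
            louvain_soft(two_triangles_bridge, hard)

    def test_rejects_non_partition(self, two_triangles_bridge):
        with pytest.raises(ValueError):
            louvain_soft(two_triangles_bridge, [{"a", "b"}])


class TestOClustR:
    def test_edgeless_graph_all_singletons(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2, 3])
        assert oclustr(g) == [{1}, {2}, {3}]

    def test_star_graph_single_cluster(self):
        clusters = oclustr(nx.star_graph(4))
        assert clusters == [{0, 1, 2, 3, 4}]

    def test_output_covers_all_nodes(self):
        for seed in range(10):
            g = random_weighted_graph(30, p=0.12, seed=100 + seed)
            assert is_cover(oclustr(g), g.nodes)

    def test_no_empty_clusters(self):
        g = random_weighted_graph(20, p=0.3, seed=3)
        assert all(oclustr(g))


class TestModularity:
    def test_single_cluster_is_zero(self, two_triangles_bridge):
        assert modularity(two_triangles_bridge,
                          [set(two_triangles_bridge.nodes)]) == pytest.approx(0.0)

    def test_two_disjoint_triangles(self, two_triangles_disjoint):
        q = modularity(two_triangles_disjoint, [{"a", "b", "c"}, {"d", "e", "f"}])
        assert q == pytest.approx(0.5)

    def test_below_one_and_matches_networkx(self):
        for seed in range(5):
            g = random_weighted_graph(20, p=0.25, seed=seed)
            if g.number_of_edges() == 0:
                continue
            clusters, q = louvain_hard(g, seed=seed)
            assert q < 1
            assert q == pytest.approx(
                nx.algorithms.community.modularity(g, clusters, weight="weight"))

    def test_membership_map_roundtrip(self):
        clusters = [{"a", "b"}, {"b", "c"}]
        memb = membership_map(clusters)
        assert memb == {"a": {0}, "b": {0, 1}, "c": {1}}
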