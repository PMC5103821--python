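import networkx as nx
import numpy as np
import pytest

from prox3c.community import GenomeSet, random_genome


@pytest.fixture
def two_triangles_bridge():
    """Two 3-cliques {a,b,c}, {d,e,f} joined by the single edge c-d."""
    g = nx.Graph()
    for e in [("a", "b"), ("b", "c"), ("a", "c"),
              ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")]:
        g.add_edge(*e, weight=1)
    return g


@pytest.fixture
def two_triangles_disjoint():
    g = nx.Graph()
    for e in [("a", "b"), ("b", "c"), ("a", "c"),
              ("d", "e"), ("e", "f"), ("d", "f")]:
        g.add_edge(*e, weight=1)
    return g


@pytest.fixture
def toy_genomes():
    """Four unrelated random 10 kb chromosomes (no shared ancestry needed)."""
    taxa = ("A", "B", "C", "D")
    return GenomeSet(taxa, {t: random_genome(10_000, i) for i, t in enumerate(taxa)})


def random_weighted_graph(n_nodes: int, p: float, seed: int) -> nx.Graph:
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                g.add_edge(i, j, weight=int(rng.integers(1, 6)))
    return g
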