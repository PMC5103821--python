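"""Graph clustering algorithms for 3C-contig graph deconvolution.

Four unsupervised algorithms are provided: Markov clustering (MCL) and a
flat (one-step) Louvain partition produce hard clusterings; Louvain-soft —
a naive overlap extension in which the two endpoints of every inter-cluster
edge gain membership in each other's cluster — and the parameter-free
OClustR graph covering produce soft (overlapping) clusterings.

Clusterings are represented as lists of node sets, ordered deterministically
by smallest member. Hard outputs partition the node set; soft outputs cover
it (every node belongs to at least one cluster).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "MCLParams",
    "MCLConvergenceError",
    "mcl",
    "louvain_hard",
    "louvain_soft",
    "oclustr",
    "modularity",
    "membership_map",
    "is_partition",
    "is_cover",
    "write_clusters",
]

Clustering = list[set]


def _canonical(clusters: list[set]) -> list[set]:
    return sorted((set(c) for c in clusters if c), key=lambda c: min(map(str, c)))


def membership_map(clusters: Clustering) -> dict:
    """node -> set of cluster indices (in canonical order)."""
    out: dict = {}
    for i, c in enumerate(clusters):
        for n in c:
            out.setdefault(n, set()).add(i)
    return out


def is_partition(clusters: Clustering, nodes) -> bool:
    seen: set = set()
    for c in clusters:
        if seen & c:
            return False
        seen |= c
    return seen == set(nodes)


def is_cover(clusters: Clustering, nodes) -> bool:
    seen: set = set()
    for c in clusters:
        seen |= c
    return seen == set(nodes)


@dataclass(frozen=True)
class MCLParams:
    """Markov clustering controls; granularity is set by ``inflation`` (> 1)."""

    inflation: float = 2.0
    expansion: int = 2
    pruning: float = 1e-5
    max_iter: int = 200
    tol: float = 1e-6
    self_loop: float = 1.0

    def __post_init__(self):
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")


class MCLConvergenceError(RuntimeError):
    def __init__(self, residual: float):
        super().__init__(f"MCL failed to converge (last residual {residual:.3g})")
        self.residual = residual


def mcl(graph: nx.Graph, params: MCLParams = MCLParams()) -> Clustering:
    """Markov clustering of the weighted graph (hard clustering).

    Self-loops of weight ``self_loop`` are added, the adjacency is made
    column-stochastic, and expansion (matrix power) alternates with
    inflation (elementwise power + renormalization) and pruning until the
    matrix is idempotent within tolerance. Clusters are read off the
    attractor structure; nodes attracted to several attractors are assigned
    to the lowest-indexed cluster so the output is a partition.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    nodes = sorted(graph.nodes, key=str)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for u, v, w in graph.edges(data="weight", default=1):
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    np.fill_diagonal(m, np.diag(m) + params.self_loop)
    m /= m.sum(axis=0, keepdims=True)
    residual = np.inf
    for _ in range(params.max_iter):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = np.power(m, params.inflation)
        m[m < params.pruning] = 0.0
        m /= m.sum(axis=0, keepdims=True)
        residual = float(np.abs(m - prev).max())
        if residual < params.tol:
            break
    else:
        raise MCLConvergenceError(residual)
    return _clusters_from_steady_state(m, nodes, hard=True)


def _clusters_from_steady_state(m: np.ndarray, nodes: list, hard: bool,
                                tol: float = 1e-6) -> Clustering:
    n = len(nodes)
    attractors = np.where(np.diag(m) > tol)[0]
    raw: list[set] = []
    for a in attractors:
        members = set(np.where(m[a, :] > tol)[0])
        members.add(int(a))
        raw.append(members)
    # merge clusters sharing an attractor (overlapping attractor systems)
    merged: list[set] = []
    for c in raw:
        hit = [k for k, d in enumerate(merged) if d & c & set(map(int, attractors))]
        if hit:
            base = merged[hit[0]]
            for k in reversed(hit[1:]):
                base |= merged.pop(k)
            base |= c
        else:
            merged.append(set(c))
    assigned = set().union(*merged) if merged else set()
    for i in range(n):
        if i not in assigned:  # numerically orphaned node: strongest column entry wins
            a = int(np.argmax(m[:, i]))
            for c in merged:
                if a in c:
                    c.add(i)
                    break
            else:
                merged.append({i})
    if hard:
        seen: set = set()
        out = []
        for c in sorted(merged, key=sorted):
            c = c - seen
            if c:
                out.append(c)
                seen |= c
        merged = out
    return _canonical([{nodes[i] for i in c} for c in merged])


def louvain_hard(graph: nx.Graph, seed: int = 0) -> tuple[Clustering, float]:
    """Flat Louvain partition maximizing weighted modularity Q.

    Returns the final top-level partition (no cluster hierarchy) and its
    modularity. Deterministic for a given seed; isolated nodes come out as
    singleton clusters. An edgeless graph yields all singletons with Q = 0.
    """
    if graph.size(weight="weight") == 0:
        return _canonical([{n} for n in graph.nodes]), 0.0
    comms = nx.algorithms.community.louvain_communities(graph, weight="weight", seed=seed)
    clusters = _canonical([set(c) for c in comms])
    return clusters, modularity(graph, clusters)


def louvain_soft(graph: nx.Graph, hard: Clustering) -> Clustering:
    """Naive soft extension of a hard partition.

    For every edge (u, v) whose endpoints lie in different hard clusters, u
    is added to v's cluster and v to u's. Original memberships are kept, so
    each soft cluster is a superset of the hard cluster at the same position.
    """
    if not is_partition(hard, graph.nodes):
        raise ValueError("hard clustering is not a partition of the graph's nodes")
    home = {n: i for i, c in enumerate(hard) for n in c}
    soft = [set(c) for c in hard]
    for u, v in graph.edges:
        if home[u] != home[v]:
            soft[home[u]].add(v)
            soft[home[v]].add(u)
    return soft


def _relevance(graph: nx.Graph) -> dict:
    """Vertex relevance: mean of relative density and relative compactness.

    Relative density compares a vertex's degree to the largest degree in its
    closed neighborhood; relative compactness is the fraction of neighbors
    with degree not exceeding the vertex's own. Hubs of locally dense stars
    score highest.
    """
    deg = dict(graph.degree)
    rel = {}
    for v in graph.nodes:
        nbrs = list(graph.neighbors(v))
        if not nbrs:
            rel[v] = 0.0
            continue
        dmax = max(deg[u] for u in nbrs + [v])
        density = deg[v] / dmax if dmax else 0.0
        compact = sum(1 for u in nbrs if deg[u] <= deg[v]) / len(nbrs)
        rel[v] = 0.5 * (density + compact)
    return rel


def oclustr(graph: nx.Graph) -> Clustering:
    """Parameter-free overlapping clustering by greedy star-subgraph covering.

    Vertices are ranked by relevance; stars (a center plus its neighbors)
    are selected greedily while uncovered vertices remain, then stars whose
    every vertex is covered by other selected stars are removed. The result
    is a cover: every node belongs to at least one cluster, and isolated
    nodes become singletons.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    rel = _relevance(graph)
    order = sorted(graph.nodes, key=lambda v: (-rel[v], -graph.degree(v), str(v)))
    covered: set = set()
    centers: list = []
    for v in order:
        star = {v} | set(graph.neighbors(v))
        if not star <= covered:
            centers.append(v)
            covered |= star
    clusters = {c: {c} | set(graph.neighbors(c)) for c in centers}
    # refinement: drop stars made redundant by the rest of the cover
    cover_count: dict = {}
    for c, members in clusters.items():
        for n in members:
            cover_count[n] = cover_count.get(n, 0) + 1
    for c in sorted(centers, key=lambda v: (rel[v], str(v))):  # least relevant first
        members = clusters[c]
        if all(cover_count[n] > 1 for n in members):
            for n in members:
                cover_count[n] -= 1
            del clusters[c]
    return _canonical(list(clusters.values()))


def modularity(graph: nx.Graph, partition: Clustering) -> float:
    """Weighted Newman modularity Q = sum_c (W_c/W - (S_c/2W)^2).

    W is the total edge weight, W_c the intra-cluster weight and S_c the
    weighted degree sum of cluster c. Q = 0 for the trivial one-cluster
    partition; Q < 1 always.
    """
    w_tot = graph.size(weight="weight")
    if w_tot == 0:
        return 0.0
    home = {n: i for i, c in enumerate(partition) for n in c}
    w_in = np.zeros(len(partition))
    s = np.zeros(len(partition))
    for u, v, w in graph.edges(data="weight", default=1):
        if home[u] == home[v]:
            w_in[home[u]] += w
    for n, d in graph.degree(weight="weight"):
        s[home[n]] += d
    return float(np.sum(w_in / w_tot - (s / (2 * w_tot)) ** 2))


def write_clusters(clusters: Clustering, path, style: str = "mcl") -> None:
    """Serialize: one cluster per line ("mcl") or (node, cluster) TSV ("tsv")."""
    with open(path, "w") as fh:
        if style == "mcl":
            for c in clusters:
                fh.write("\t".join(sorted(map(str, c))) + "\n")
        elif style == "tsv":
            for i, c in enumerate(clusters):
                for n in sorted(map(str, c)):
                    fh.write(f"{n}\t{i}\n")
        else:
            raise ValueError(f"unknown style {style!r}")
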