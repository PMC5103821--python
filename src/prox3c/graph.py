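"""The 3C-contig graph.

Nodes are assembly contigs (all of them — isolated contigs are kept);
undirected edges count accepted 3C read-pairs whose two ends map to two
*different* contigs. Intra-contig pairs carry no linkage information and
are discarded. Raw counts are used as weights: no contact-map
normalization is applied.

Mapping acceptance follows a strict default policy: a pair is accepted only
if both ends align with 100% read coverage and zero mismatches. The policy
is relaxable for real (noisy) data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "MappedPair",
    "MappingPolicy",
    "GraphSummary",
    "filter_mapping",
    "build_graph",
    "prune_edges",
    "graph_summary",
    "pairs_from_sam",
    "pairs_from_tsv",
    "write_edge_list",
]


@dataclass(frozen=True)
class MappedPair:
    """A 3C read-pair mapped onto contigs (either end may be unmapped)."""

    pair_id: str
    contig1: str | None
    contig2: str | None
    cov1: float = 1.0
    cov2: float = 1.0
    nm1: int = 0
    nm2: int = 0


@dataclass(frozen=True)
class MappingPolicy:
    """Acceptance thresholds for mapped pairs (defaults: perfect matches only)."""

    min_coverage: float = 1.0
    max_mismatches: int = 0


def filter_mapping(pair: MappedPair, policy: MappingPolicy = MappingPolicy()) -> bool:
    """Accept a pair iff both ends meet the coverage and mismatch thresholds."""
    if pair.contig1 is None or pair.contig2 is None:
        return False
    return (pair.cov1 >= policy.min_coverage and pair.cov2 >= policy.min_coverage
            and pair.nm1 <= policy.max_mismatches and pair.nm2 <= policy.max_mismatches)


def build_graph(pairs: Iterable[tuple[str, str]], contigs: Mapping[str, int]) -> nx.Graph:
    """Build the weighted 3C-contig graph from accepted contig pairs.

    ``contigs`` maps every contig id to its length (bp); all contigs become
    nodes even if no pair touches them. Pairs linking a contig to itself
    are ignored; w_ij counts pairs linking contigs i != j.
    """
    g = nx.Graph()
    for cid, length in contigs.items():
        g.add_node(cid, length=int(length))
    for c1, c2 in pairs:
        if c1 not in g or c2 not in g:
            missing = c1 if c1 not in g else c2
            raise KeyError(f"pair references unknown contig {missing!r}")
        if c1 == c2:
            continue
        if g.has_edge(c1, c2):
            g[c1][c2]["weight"] += 1
        else:
            g.add_edge(c1, c2, weight=1)
    return g


def prune_edges(graph: nx.Graph, min_weight: int) -> nx.Graph:
    """Drop edges with weight below ``min_weight``; all nodes are retained."""
    if min_weight < 1:
        raise ValueError("min_weight must be >= 1")
    out = graph.copy()
    drop = [(u, v) for u, v, w in out.edges(data="weight") if w < min_weight]
    out.remove_edges_from(drop)
    return out


@dataclass(frozen=True)
class GraphSummary:
    order: int
    size: int
    density: float
    total_weight: float


def graph_summary(graph: nx.Graph) -> GraphSummary:
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    density = 2.0 * m / (n * (n - 1)) if n >= 2 else 0.0
    return GraphSummary(n, m, density, float(graph.size(weight="weight")))


def pairs_from_sam(path, include_secondary: bool = False) -> list[MappedPair]:
    """Read mapped pairs from a (name-grouped) SAM/BAM of 3C read mappings.

    Per-end coverage is the aligned fraction of the read (soft/hard clips
    reduce it); mismatches come from the NM tag. Secondary and
    supplementary alignments are ignored unless requested; reads whose mate
    is unmapped yield a pair with one ``None`` end.
    """
    import pysam

    ends: dict[str, dict[int, tuple[str | None, float, int]]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if not include_secondary and (aln.is_secondary or aln.is_supplementary):
                continue
            name = aln.query_name
            mate = 2 if aln.is_read2 else 1
            if aln.is_unmapped:
                rec = (None, 0.0, 0)
            else:
                read_len = aln.infer_read_length() or aln.query_length
                cov = aln.query_alignment_length / read_len if read_len else 0.0
                nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
                rec = (aln.reference_name, cov, int(nm))
            ends.setdefault(name, {})[mate] = rec
    out = []
    for name in sorted(ends):
        e1 = ends[name].get(1, (None, 0.0, 0))
        e2 = ends[name].get(2, (None, 0.0, 0))
        out.append(MappedPair(name, e1[0], e2[0], e1[1], e2[1], e1[2], e2[2]))
    return out


def pairs_from_tsv(path) -> list[MappedPair]:
    """Plain-text mapping dialect: read_id, contig1, contig2, cov1, cov2, nm1, nm2."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.startswith("read_id"):
                continue
            rid, c1, c2, cov1, cov2, nm1, nm2 = line.rstrip("\n").split("\t")
            out.append(MappedPair(rid, c1 if c1 != "." else None, c2 if c2 != "." else None,
                                  float(cov1), float(cov2), int(nm1), int(nm2)))
    return out


def write_edge_list(graph: nx.Graph, edge_path, node_path=None) -> None:
    """Serialize as a 3-column weighted edge TSV plus an optional node table."""
    with open(edge_path, "w") as fh:
        for u, v, w in sorted(graph.edges(data="weight")):
            fh.write(f"{u}\t{v}\t{w}\n")
    if node_path is not None:
        with open(node_path, "w") as fh:
            for n, data in sorted(graph.nodes(data=True)):
                fh.write(f"{n}\t{data.get('length', 0)}\n")
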