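"""Parameter-sweep orchestration.

Enumerates the benchmark grid (tree topology x abundance profile x
divergence alpha_BL x WGS depth x 3C depth), runs the end-to-end pipeline
for each combination and joins clustering validation scores with assembly
and graph complexity metrics into one tidy results table.

Two execution paths exist for the assembly/mapping stages:

* the *fixture* path (default, self-contained): ``synth_contigs`` emulates
  metagenome co-assembly by fragmenting the ancestral coordinate space and
  collapsing homologous fragments whose cross-taxon identity reaches a
  merge threshold into single shared contigs — producing an overlapping
  gold standard without running an assembler — and 3C read-pairs are placed
  onto contigs by their truth coordinates (reads straddling a contig
  boundary are unmapped, mirroring the 100%-coverage acceptance rule);
* the *external* path, where pre-computed contigs (FASTA), read mappings
  (SAM/BAM) and contig-vs-reference alignments are supplied by outside
  tools and ingested through the graph and validation modules.
"""

from __future__ import annotations

import itertools
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import graph as _graph
from . import metrics as _metrics
from .community import (EvoParams, GenomeSet, LineageMap,
                        build_tree, evolve, make_profile, pairwise_identity,
                        random_genome, scaled_evo_params)
from .readsim import C3Params, ReadPairSet, sim_3c
from .validate import GoldStandard, weighted_bcubed

__all__ = [
    "SweepConfig",
    "RunSpec",
    "ContigCatalog",
    "enumerate_runs",
    "synth_contigs",
    "map_pairs_by_truth",
    "source_counts",
    "lineage_gold_standard",
    "run_pipeline",
    "sweep",
]

_PAPER_ALPHAS = tuple(float(a) for a in np.geomspace(0.025, 1.0, 10))


@dataclass(frozen=True)
class SweepConfig:
    """The benchmark grid; defaults reproduce the published sweep shape."""

    trees: tuple[str, ...] = ("star", "ladder")
    profiles: tuple[str, ...] = ("uniform", "exp_decay")
    alpha_bl: tuple[float, ...] = _PAPER_ALPHAS
    xfold: tuple[float, ...] = (10, 50, 100)
    n3c: tuple[int, ...] = (10_000, 20_000, 50_000, 100_000, 1_000_000)
    algorithms: tuple[str, ...] = ("mcl", "louvain-hard", "louvain-soft", "oclustr")
    inflations: tuple[float, ...] = tuple(float(x) for x in np.linspace(1.1, 2.0, 5))
    master_seed: int = 1
    n_taxa: int = 4
    ell: float = 0.08
    ancestor_len: int = 3_000_000

    def n_communities(self) -> int:
        return len(self.trees) * len(self.profiles) * len(self.alpha_bl)

    def n_readsets(self) -> int:
        return self.n_communities() * len(self.xfold)

    def n_runs(self) -> int:
        return self.n_readsets() * len(self.n3c)

    def n_clusterings(self, algorithm: str) -> int:
        per_run = len(self.inflations) if algorithm in ("mcl", "srmcl") else 1
        return self.n_runs() * per_run


@dataclass(frozen=True)
class RunSpec:
    index: int
    tree: str
    profile: str
    alpha_bl: float
    xfold: float
    n3c: int
    seed: int


def enumerate_runs(config: SweepConfig) -> list[RunSpec]:
    """Cartesian product of the grid in level order, with derived child seeds."""
    for name in ("trees", "profiles", "alpha_bl", "xfold", "n3c"):
        if not getattr(config, name):
            raise ValueError(f"empty grid dimension: {name}")
    runs = []
    combos = itertools.product(config.trees, config.profiles, config.alpha_bl,
                               config.xfold, config.n3c)
    for i, (tree, prof, alpha, xf, n3c) in enumerate(combos):
        ss = np.random.SeedSequence(config.master_seed, spawn_key=(i,))
        seed = int(ss.generate_state(1)[0] % (2**31))
        runs.append(RunSpec(i, tree, prof, float(alpha), float(xf), int(n3c), seed))
    return runs


@dataclass
class ContigCatalog:
    """Assembler-free contig catalogue with overlap-aware truth classes.

    ``classes`` maps each contig to the set of taxa whose homologous copies
    co-assembled into it; ``images`` gives, per taxon, the half-open
    descendant intervals labeled with the contig covering them (a partition
    of each descendant chromosome).
    """

    lengths: dict[str, int]
    classes: dict[str, frozenset]
    images: dict[str, list[tuple[int, int, str]]]  # taxon -> sorted (start, end, contig)
    _starts: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for t, ivs in self.images.items():
            self._starts[t] = np.array([s for s, _, _ in ivs], dtype=np.int64)

    def locate(self, taxon: str, pos: np.ndarray, read_len: int) -> list[str | None]:
        """Contig fully containing [pos, pos+read_len) per position, else None."""
        ivs = self.images[taxon]
        idx = np.searchsorted(self._starts[taxon], pos, side="right") - 1
        out: list[str | None] = []
        for p, i in zip(np.atleast_1d(pos), np.atleast_1d(idx)):
            if i < 0:
                out.append(None)
                continue
            s, e, cid = ivs[i]
            out.append(cid if p + read_len <= e else None)
        return out


def _fragment_root(ancestor_len: int, frag_mean: float, min_len: int,
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    if frag_mean < min_len:
        raise ValueError("frag_mean below the minimum contig length floor")
    edges = [0]
    while edges[-1] < ancestor_len:
        edges.append(edges[-1] + max(min_len, int(rng.exponential(frag_mean))))
    edges[-1] = ancestor_len
    if len(edges) > 2 and edges[-1] - edges[-2] < min_len:
        del edges[-2]
    return list(zip(edges[:-1], edges[1:]))


def synth_contigs(genomes: GenomeSet, lineage: LineageMap, ancestor_len: int,
                  frag_mean: float = 5_000, ani_merge_threshold: float = 0.96,
                  seed: int = 0, min_len: int = 500) -> ContigCatalog:
    """Emulate metagenome co-assembly from simulator truth.

    The ancestral coordinate space is fragmented into exponential-length
    pieces; within each fragment, descendant copies whose pairwise identity
    (from the lineage map) reaches ``ani_merge_threshold`` are collapsed by
    single linkage into one shared contig carrying all source classes —
    conserved sequence co-assembles, diverged sequence does not. Taxon-
    specific insertions (HT, indels) ride along with their flanking contig.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    frags = _fragment_root(ancestor_len, frag_mean, min_len, rng)
    taxa = list(genomes.taxa)
    # per-taxon anc pieces within each fragment, in descendant coordinates
    pieces: dict[str, list[tuple[int, int, int]]] = {t: [] for t in taxa}  # (d_start, d_end, frag_idx)
    frag_edges = np.array([a for a, _ in frags] + [ancestor_len])
    for t in taxa:
        for d_start, d_end, seg in lineage.intervals(t):
            if seg.source != "ancestor":
                continue
            # split the segment at fragment boundaries (root coordinates)
            r = seg.root_start
            while r < seg.root_end:
                fi = bisect_right(frag_edges.tolist(), r) - 1
                r_next = min(seg.root_end, int(frag_edges[fi + 1]))
                if seg.strand > 0:
                    ds = d_start + (r - seg.root_start)
                    de = ds + (r_next - r)
                else:
                    de = d_end - (r - seg.root_start)
                    ds = de - (r_next - r)
                pieces[t].append((ds, de, fi))
                r = r_next
    # group taxa per fragment by single-linkage on pairwise lineage identity
    lengths: dict[str, int] = {}
    classes: dict[str, frozenset] = {}
    piece_contig: dict[str, dict[tuple[int, int], str]] = {t: {} for t in taxa}
    for fi, (a, b) in enumerate(frags):
        present = [t for t in taxa if any(p[2] == fi for p in pieces[t])]
        if not present:
            continue
        groups: list[set] = []
        for t in present:
            placed = False
            for grp in groups:
                if any(pairwise_identity(lineage, t, u, a, b) >= ani_merge_threshold
                       for u in grp):
                    grp.add(t)
                    placed = True
                    break
            if not placed:
                groups.append({t})
        for gi, grp in enumerate(sorted(groups, key=lambda g: sorted(g)[0])):
            cid = f"f{fi}g{gi}"
            rep = sorted(grp)[0]
            span = sum(de - ds for ds, de, f in pieces[rep] if f == fi)
            lengths[cid] = max(span, 1)
            classes[cid] = frozenset(grp)
            for t in grp:
                for ds, de, f in pieces[t]:
                    if f == fi:
                        piece_contig[t][(ds, de)] = cid
    # build per-taxon interval images; non-anc gaps extend the preceding piece
    images: dict[str, list[tuple[int, int, str]]] = {}
    for t in taxa:
        ivs = sorted((ds, de, cid) for (ds, de), cid in piece_contig[t].items())
        merged: list[list] = []
        cursor = 0
        for ds, de, cid in ivs:
            if ds > cursor and merged:
                merged[-1][1] = ds  # absorb the insertion into the left contig
            if merged and merged[-1][2] == cid and merged[-1][1] >= ds:
                merged[-1][1] = max(merged[-1][1], de)
            else:
                start = ds if merged else 0
                merged.append([start, de, cid])
            cursor = de
        total = len(genomes.sequences[t])
        if merged:
            merged[-1][1] = max(merged[-1][1], total)
        else:
            merged.append([0, total, f"orphan_{t}"])
            lengths[f"orphan_{t}"] = total
            classes[f"orphan_{t}"] = frozenset({t})
        images[t] = [(int(s), int(e), c) for s, e, c in merged]
    return ContigCatalog(lengths, classes, images)


def map_pairs_by_truth(pairs: ReadPairSet, catalog: ContigCatalog) -> list[tuple[str, str]]:
    """Place error-free read-pairs onto contigs via their truth coordinates.

    Both ends must lie fully inside one contig image (reads crossing a
    contig boundary or the origin are unmapped and the pair is dropped —
    the truth-path analogue of the strict full-coverage mapping policy).
    """
    out = []
    for ti in np.unique(pairs.taxon):
        taxon = pairs.taxon_names[ti]
        sel = pairs.taxon == ti
        c1 = catalog.locate(taxon, pairs.pos1[sel], pairs.read_len)
        c2 = catalog.locate(taxon, pairs.pos2[sel], pairs.read_len)
        out.extend((a, b) for a, b in zip(c1, c2) if a is not None and b is not None)
    return out


def source_counts(pairs: ReadPairSet, catalog: ContigCatalog) -> _metrics.ContigSourceCounts:
    """Per-contig read counts by source genome (both ends counted)."""
    contigs = sorted(catalog.lengths)
    genomes = tuple(pairs.taxon_names)
    cix = {c: i for i, c in enumerate(contigs)}
    counts = np.zeros((len(contigs), len(genomes)))
    for ti in np.unique(pairs.taxon):
        taxon = pairs.taxon_names[ti]
        sel = pairs.taxon == ti
        for pos_col in (pairs.pos1[sel], pairs.pos2[sel]):
            for cid in catalog.locate(taxon, pos_col, pairs.read_len):
                if cid is not None:
                    counts[cix[cid], ti] += 1
    return _metrics.ContigSourceCounts(
        tuple(contigs), genomes,
        np.array([catalog.lengths[c] for c in contigs], dtype=float), counts)


def lineage_gold_standard(catalog: ContigCatalog) -> GoldStandard:
    """Gold standard straight from the simulator-side truth classes."""
    return GoldStandard(dict(catalog.classes),
                        {c: float(l) for c, l in catalog.lengths.items()})


def run_pipeline(spec: RunSpec, config: SweepConfig,
                 evo_params: EvoParams | None = None,
                 c3_params: C3Params | None = None,
                 frag_mean: float = 5_000,
                 ani_merge_threshold: float = 0.96,
                 algorithms: tuple[str, ...] | None = None) -> list[dict]:
    """Execute one sweep cell on the fixture path; one result row per clustering.

    Stages: ancestral genome -> evolved community -> synthetic co-assembly
    -> 3C read simulation -> truth mapping -> 3C-contig graph -> clustering
    -> weighted-Bcubed validation + complexity metrics.
    """
    if evo_params is None:
        evo_params = scaled_evo_params(EvoParams(), config.ancestor_len)
    if c3_params is None:
        c3_params = C3Params()
    if algorithms is None:
        algorithms = config.algorithms
    ss = np.random.SeedSequence(spec.seed)
    seeds = [int(s % (2**31)) for s in ss.generate_state(5)]
    ancestor = random_genome(config.ancestor_len, seeds[0])
    tree = build_tree(spec.tree, config.n_taxa, config.ell, spec.alpha_bl)
    profile = make_profile(spec.profile, config.n_taxa, tree.taxa)
    genomes, lineage = evolve(ancestor, tree, evo_params, seeds[1])
    catalog = synth_contigs(genomes, lineage, config.ancestor_len,
                            frag_mean=frag_mean,
                            ani_merge_threshold=ani_merge_threshold, seed=seeds[2])
    pairs = sim_3c(genomes, profile, spec.n3c, c3_params, seeds[3],
                   emit_sequences=False)
    g = _graph.build_graph(map_pairs_by_truth(pairs, catalog), catalog.lengths)
    summary = _graph.graph_summary(g)
    gold = lineage_gold_standard(catalog)
    sc = source_counts(pairs, catalog)
    smix = _metrics.s_mixing(sc, profile)
    h_l = _metrics.laplacian_entropy(g)
    n50, l50 = _metrics.n50_l50(list(catalog.lengths.values()))
    base = {
        "run": spec.index, "tree": spec.tree, "profile": spec.profile,
        "alpha_bl": spec.alpha_bl, "xfold": spec.xfold, "n3c": spec.n3c,
        "seed": spec.seed, "order": summary.order, "size": summary.size,
        "density": summary.density, "total_weight": summary.total_weight,
        "h_l": h_l, "s_mixing": smix, "n50": n50, "l50": l50,
    }
    rows = []
    hard_cache: tuple[_cluster.Clustering, float] | None = None
    for algo in algorithms:
        if algo == "mcl":
            for infl in config.inflations:
                clusters = _cluster.mcl(g, _cluster.MCLParams(inflation=infl))
                sc_b3 = weighted_bcubed(clusters, gold)
                rows.append({**base, "algorithm": "mcl", "inflation": infl,
                             "modularity": _cluster.modularity(g, clusters),
                             "p_b3": sc_b3.precision, "r_b3": sc_b3.recall,
                             "f_b3": sc_b3.f})
            continue
        if algo in ("louvain-hard", "louvain-soft"):
            if hard_cache is None:
                hard_cache = _cluster.louvain_hard(g, seed=seeds[4])
            hard, q = hard_cache
            clusters = hard if algo == "louvain-hard" else _cluster.louvain_soft(g, hard)
            mod = q
        elif algo == "oclustr":
            clusters = _cluster.oclustr(g)
            mod = None
        else:
            raise ValueError(f"unknown algorithm {algo!r}")
        sc_b3 = weighted_bcubed(clusters, gold)
        rows.append({**base, "algorithm": algo, "inflation": None,
                     "modularity": mod, "p_b3": sc_b3.precision,
                     "r_b3": sc_b3.recall, "f_b3": sc_b3.f})
    return rows


def sweep(config: SweepConfig, **pipeline_kwargs) -> pd.DataFrame:
    """Run the full grid on the fixture path and return the tidy result table."""
    rows = []
    for spec in enumerate_runs(config):
        rows.extend(run_pipeline(spec, config, **pipeline_kwargs))
    return pd.DataFrame(rows)
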