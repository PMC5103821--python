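"""Simulated microbial communities.

Builds small phylogenies (star / ladder topologies), scales their branch
lengths by a single divergence factor ``alpha_bl``, evolves descendant
genomes from a circular ancestral chromosome under a Jukes-Cantor
substitution model plus structural events (indels, horizontal-transfer
insertions, inversions), and produces community abundance profiles.

Every descendant base carries provenance: the lineage map records, for each
interval of each descendant, the ancestral interval (or HT/indel origin) it
derives from together with an identity fraction relative to that source.
This simulator-side truth is what downstream fixtures use as a gold
standard, so no aligner is required to know where a contig came from.
"""

from __future__ import annotations

import string
from bisect import bisect_right
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhyloTree",
    "EvoParams",
    "GenomeSet",
    "Segment",
    "LineageMap",
    "AbundanceProfile",
    "build_tree",
    "make_profile",
    "evolve",
    "random_genome",
    "scaled_evo_params",
    "mean_pairwise_identity",
]

# base encoding: A=0 C=1 G=2 T=3; complement is 3 - code
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 code array (A=0,C=1,G=2,T=3)."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        bad = chr(np.frombuffer(seq.encode(), dtype=np.uint8)[arr == 255][0])
        raise ValueError(f"non-ACGT character in sequence: {bad!r}")
    return arr


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def random_genome(length: int, seed: int) -> np.ndarray:
    """Uniform-random circular chromosome as a code array."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _taxon_names(n: int) -> tuple[str, ...]:
    if n <= 26:
        return tuple(string.ascii_uppercase[:n])
    return tuple(f"T{i}" for i in range(n))


@dataclass(frozen=True)
class PhyloTree:
    """Rooted tree with scaled branch lengths.

    ``parent`` maps every non-root node to its parent; ``lengths`` gives the
    branch length (expected substitutions/site, already multiplied by
    ``alpha_bl``) of the edge above each non-root node.
    """

    topology: str
    taxa: tuple[str, ...]
    parent: dict[str, str]
    lengths: dict[str, float]
    ell: float
    alpha_bl: float

    @property
    def nodes(self) -> tuple[str, ...]:
        return ("root",) + tuple(self.parent)

    def children(self, node: str) -> list[str]:
        return [c for c, p in self.parent.items() if p == node]

    def depth(self, node: str) -> float:
        d = 0.0
        while node != "root":
            d += self.lengths[node]
            node = self.parent[node]
        return d

    def to_newick(self) -> str:
        def sub(node: str) -> str:
            kids = self.children(node)
            label = "" if node.startswith("_") or node == "root" else node
            if not kids:
                return f"{label}:{self.lengths[node]:g}"
            inner = ",".join(sub(k) for k in kids)
            if node == "root":
                return f"({inner}){label};"
            return f"({inner}){label}:{self.lengths[node]:g}"

        return sub("root")


def build_tree(topology: str, n_taxa: int, ell: float, alpha_bl: float) -> PhyloTree:
    """Build a star or ladder phylogeny with branch lengths scaled by alpha_bl.

    Star: all leaves attach to the root at distance ``alpha_bl * ell``.

    Ladder (4 taxa only): an ultrametric caterpillar of height 1.5*ell in
    which successive leaf-to-nearest-ancestor distances decrease in steps of
    ell/2 (1.5*ell, ell, 0.5*ell, 0.5*ell) so that taxon B's branch equals
    the star branch length.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if ell <= 0 or alpha_bl <= 0:
        raise ValueError("ell and alpha_bl must be positive")
    taxa = _taxon_names(n_taxa)
    s = alpha_bl * ell
    if topology == "star":
        parent = {t: "root" for t in taxa}
        lengths = {t: s for t in taxa}
    elif topology == "ladder":
        if n_taxa != 4:
            raise ValueError("ladder topology is defined for exactly 4 taxa")
        a, b, c, d = taxa
        parent = {a: "root", "_y": "root", b: "_y", "_x": "_y", c: "_x", d: "_x"}
        lengths = {a: 1.5 * s, "_y": 0.5 * s, b: s, "_x": 0.5 * s, c: 0.5 * s, d: 0.5 * s}
    else:
        raise ValueError(f"unsupported topology: {topology!r}")
    return PhyloTree(topology, taxa, parent, lengths, ell, alpha_bl)


@dataclass(frozen=True)
class AbundanceProfile:
    """Per-taxon relative abundances; ``raw`` scaled so max = 1."""

    kind: str
    taxa: tuple[str, ...]
    raw: np.ndarray
    normalized: np.ndarray

    def __post_init__(self):
        assert abs(self.normalized.sum() - 1.0) < 1e-12


def make_profile(kind: str, n_taxa: int, taxa: tuple[str, ...] | None = None) -> AbundanceProfile:
    """Uniform profile or abundances decaying by factors of 1/e."""
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if kind == "uniform":
        raw = np.ones(n_taxa)
    elif kind == "exp_decay":
        raw = np.exp(-np.arange(n_taxa, dtype=float))
    else:
        raise ValueError(f"unknown profile kind: {kind!r}")
    if taxa is None:
        taxa = _taxon_names(n_taxa)
    return AbundanceProfile(kind, tuple(taxa), raw, raw / raw.sum())


@dataclass(frozen=True)
class EvoParams:
    """Rates and size distributions of the simulated evolutionary events.

    ``sub_rate`` converts branch length into expected substitutions per site
    (1.0 means branch lengths are in substitutions/site). Each structural
    event class (indel, small HT, large HT, inversion) occurs at Poisson
    rate branch_length * L * sub_rate * event_scale per branch.
    """

    sub_rate: float = 1.0
    event_scale: float = 1e-4
    indel_size_mean: float = 10.0
    small_ht_size_mean: float = 200.0
    large_ht_range: tuple[int, int] = (10_000, 60_000)
    inversion_size_mean: float = 50_000.0
    max_retries: int = 100

    def __post_init__(self):
        if self.large_ht_range[0] >= self.large_ht_range[1]:
            raise ValueError("large_ht_range must satisfy low < high")
        if min(self.indel_size_mean, self.small_ht_size_mean, self.inversion_size_mean) <= 0:
            raise ValueError("event size parameters must be positive")


def scaled_evo_params(base: EvoParams, ancestor_len: int, reference_len: int = 3_000_000) -> EvoParams:
    """Rescale structural-event sizes for a smaller-than-reference ancestor.

    Event *rates* per base are unchanged; only the size distributions shrink
    by the genome-length ratio so that events remain proportionate.
    """
    f = ancestor_len / reference_len
    lo, hi = base.large_ht_range
    return replace(
        base,
        small_ht_size_mean=max(10.0, base.small_ht_size_mean * f),
        large_ht_range=(max(50, int(lo * f)), max(100, int(hi * f))),
        inversion_size_mean=max(50.0, base.inversion_size_mean * f),
    )


@dataclass
class Segment:
    """One provenance interval of a descendant chromosome.

    ``source`` is "ancestor" (with 0-based half-open root interval and
    strand), "ht" (horizontal transfer from a random donor pool) or "indel"
    (small de-novo insertion). ``identity`` is the fraction of bases still
    matching the source sequence.
    """

    length: int
    source: str
    root_start: int = -1
    root_end: int = -1
    strand: int = 1
    identity: float = 1.0
    donor: str = ""

    def clone(self) -> "Segment":
        return Segment(self.length, self.source, self.root_start, self.root_end,
                       self.strand, self.identity, self.donor)


@dataclass
class LineageMap:
    """Per-taxon ordered provenance segments covering each descendant."""

    segments: dict[str, list[Segment]]

    def intervals(self, taxon: str) -> list[tuple[int, int, Segment]]:
        out, pos = [], 0
        for seg in self.segments[taxon]:
            out.append((pos, pos + seg.length, seg))
            pos += seg.length
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\tstart\tend\tsource\tidentity\n")
            for taxon in self.segments:
                for s, e, seg in self.intervals(taxon):
                    if seg.source == "ancestor":
                        tag = f"ancestor:{seg.root_start}-{seg.root_end}:{'+' if seg.strand > 0 else '-'}"
                    elif seg.source == "ht":
                        tag = f"ht:{seg.donor}"
                    else:
                        tag = "indel"
                    fh.write(f"{taxon}\t{s}\t{e}\t{tag}\t{seg.identity:.6f}\n")


@dataclass
class GenomeSet:
    """Evolved descendant chromosomes (one circular chromosome per taxon)."""

    taxa: tuple[str, ...]
    sequences: dict[str, np.ndarray]
    event_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {t: len(self.sequences[t]) for t in self.taxa}

    def fasta_records(self):
        for t in self.taxa:
            yield t, codes_to_seq(self.sequences[t])

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.fasta_records():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")


class _Chrom:
    """Mutable chromosome with synchronized sequence and provenance segments."""

    def __init__(self, seq: np.ndarray, segs: list[Segment]):
        self.seq = seq
        self.segs = segs

    def __len__(self):
        return len(self.seq)

    def _starts(self) -> list[int]:
        starts, pos = [], 0
        for seg in self.segs:
            starts.append(pos)
            pos += seg.length
        return starts

    def _split_at(self, pos: int) -> int:
        """Ensure a segment boundary at ``pos``; return index of segment starting there."""
        starts = self._starts()
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return 0
        if starts[i] == pos:
            return i
        if pos >= len(self.seq):
            return len(self.segs)
        seg = self.segs[i]
        off = pos - starts[i]
        left = seg.clone()
        right = seg.clone()
        left.length, right.length = off, seg.length - off
        if seg.source == "ancestor":
            if seg.strand > 0:
                left.root_end = seg.root_start + off
                right.root_start = seg.root_start + off
            else:
                # reverse strand: descendant start corresponds to root end
                left.root_start = seg.root_end - off
                right.root_end = seg.root_end - off
        self.segs[i:i + 1] = [left, right]
        return i + 1

    def delete(self, a: int, b: int) -> None:
        i = self._split_at(a)
        j = self._split_at(b)
        del self.segs[i:j]
        self.seq = np.concatenate([self.seq[:a], self.seq[b:]])

    def insert(self, pos: int, ins_seq: np.ndarray, seg: Segment) -> None:
        i = self._split_at(pos)
        self.segs.insert(i, seg)
        self.seq = np.concatenate([self.seq[:pos], ins_seq, self.seq[pos:]])

    def invert(self, a: int, b: int) -> None:
        i = self._split_at(a)
        j = self._split_at(b)
        inverted = []
        for seg in reversed(self.segs[i:j]):
            seg = seg.clone()
            seg.strand = -seg.strand
            inverted.append(seg)
        self.segs[i:j] = inverted
        self.seq = np.concatenate([self.seq[:a], 3 - self.seq[a:b][::-1], self.seq[b:]])

    def substitute(self, positions: np.ndarray, rng: np.random.Generator) -> None:
        if positions.size == 0:
            return
        self.seq[positions] = (self.seq[positions] + rng.integers(1, 4, positions.size)) % 4
        # degrade identity of hit segments (approximate: repeat hits at one
        # site are counted again, a negligible bias at the rates used here)
        starts = np.array(self._starts())
        idx = np.searchsorted(starts, positions, side="right") - 1
        hits = np.bincount(idx, minlength=len(self.segs))
        for k, h in enumerate(hits):
            if h:
                seg = self.segs[k]
                seg.identity = max(0.0, seg.identity * (1.0 - h / seg.length))


def _evolve_branch(chrom: _Chrom, branch_len: float, params: EvoParams,
                   rng: np.random.Generator, counts: dict[str, int]) -> None:
    L = len(chrom)
    lam = branch_len * L * params.sub_rate
    lam_ev = lam * params.event_scale
    n_indel = rng.poisson(lam_ev)
    n_sht = rng.poisson(lam_ev)
    n_lht = rng.poisson(lam_ev)
    n_inv = rng.poisson(lam_ev)
    events = (["indel"] * n_indel + ["small_ht"] * n_sht
              + ["large_ht"] * n_lht + ["inversion"] * n_inv)
    rng.shuffle(events)
    for ev in events:
        _apply_event(chrom, ev, params, rng)
        counts[ev] = counts.get(ev, 0) + 1
    n_sub = rng.poisson(branch_len * len(chrom) * params.sub_rate)
    chrom.substitute(rng.integers(0, len(chrom), n_sub), rng)
    counts["substitution"] = counts.get("substitution", 0) + int(n_sub)


def _draw_size(kind: str, params: EvoParams, rng: np.random.Generator) -> int:
    if kind == "indel":
        return int(rng.geometric(1.0 / params.indel_size_mean))
    if kind == "small_ht":
        return max(1, int(rng.poisson(params.small_ht_size_mean)))
    if kind == "large_ht":
        return int(rng.integers(params.large_ht_range[0], params.large_ht_range[1] + 1))
    return int(rng.geometric(1.0 / params.inversion_size_mean))


def _apply_event(chrom: _Chrom, kind: str, params: EvoParams, rng: np.random.Generator) -> None:
    L = len(chrom)
    for _ in range(params.max_retries):
        size = _draw_size(kind, params, rng)
        if kind in ("inversion",) or (kind == "indel" and rng.random() < 0.5):
            # in-place events need the span to fit on the linearized ring
            if size >= L:
                continue
            a = int(rng.integers(0, L - size))
            if kind == "inversion":
                chrom.invert(a, a + size)
            else:
                chrom.delete(a, a + size)
            return
        # insertions: small indel insertions and HT from a random donor pool
        pos = int(rng.integers(0, L + 1))
        ins = rng.integers(0, 4, size=size, dtype=np.uint8)
        if kind == "indel":
            seg = Segment(size, "indel")
        else:
            donor = f"donor{rng.integers(0, 2**31)}"
            seg = Segment(size, "ht", donor=donor)
        chrom.insert(pos, ins, seg)
        return
    raise RuntimeError(f"could not place {kind} event after {params.max_retries} retries")


def evolve(ancestor: np.ndarray | str, tree: PhyloTree, params: EvoParams,
           seed: int) -> tuple[GenomeSet, LineageMap]:
    """Evolve one descendant chromosome per leaf of ``tree``.

    Along each branch, the substitution count is Poisson(branch_length * L *
    sub_rate) and each structural event class is Poisson with that mean
    times ``event_scale``. Identical seeds give byte-identical outputs.
    """
    if isinstance(ancestor, str):
        ancestor = seq_to_codes(ancestor)
    if len(ancestor) == 0:
        raise ValueError("ancestor sequence is empty")
    root = _Chrom(ancestor.copy(), [Segment(len(ancestor), "ancestor", 0, len(ancestor), 1, 1.0)])
    states: dict[str, _Chrom] = {"root": root}
    counts: dict[str, dict[str, int]] = {}
    # deterministic breadth-first branch order; per-branch child RNG streams
    order: list[str] = []
    frontier = ["root"]
    while frontier:
        node = frontier.pop(0)
        kids = sorted(c for c, p in tree.parent.items() if p == node)
        order.extend(kids)
        frontier.extend(kids)
    for k, node in enumerate(order):
        parent_state = states[tree.parent[node]]
        chrom = _Chrom(parent_state.seq.copy(), [s.clone() for s in parent_state.segs])
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
        c: dict[str, int] = {}
        _evolve_branch(chrom, tree.lengths[node], params, rng, c)
        states[node] = chrom
        counts[node] = c
    genomes = GenomeSet(tree.taxa, {t: states[t].seq for t in tree.taxa},
                        {t: counts[t] for t in tree.taxa})
    lineage = LineageMap({t: states[t].segs for t in tree.taxa})
    return genomes, lineage


def _identity_in_window(lineage: LineageMap, taxon: str, lo: int, hi: int) -> tuple[float, float]:
    """(coverage fraction, mean identity) of a root window in one descendant."""
    covered = 0
    weighted = 0.0
    for _, _, seg in lineage.intervals(taxon):
        if seg.source != "ancestor":
            continue
        a, b = max(seg.root_start, lo), min(seg.root_end, hi)
        if a < b:
            covered += b - a
            weighted += (b - a) * seg.identity
    if covered == 0:
        return 0.0, 0.0
    return covered / (hi - lo), weighted / covered


def pairwise_identity(lineage: LineageMap, t1: str, t2: str, lo: int, hi: int) -> float:
    """Approximate identity between two descendants over a root window.

    Each copy diverged independently from the ancestor, so the pairwise
    identity is approximated by the product of per-copy identities, scaled
    by the smaller root-window coverage.
    """
    c1, i1 = _identity_in_window(lineage, t1, lo, hi)
    c2, i2 = _identity_in_window(lineage, t2, lo, hi)
    return min(c1, c2) * i1 * i2


def mean_pairwise_identity(lineage: LineageMap, ancestor_len: int, n_windows: int = 20) -> float:
    """Mean pairwise descendant identity over root windows (truth-derived ANI proxy)."""
    taxa = list(lineage.segments)
    edges = np.linspace(0, ancestor_len, n_windows + 1).astype(int)
    vals = []
    for a, b in zip(edges[:-1], edges[1:]):
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                vals.append(pairwise_identity(lineage, taxa[i], taxa[j], int(a), int(b)))
    return float(np.mean(vals))
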