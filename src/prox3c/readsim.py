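"""Abundance-weighted read simulation.

Two simulators operate directly on evolved community genomes:

* ``sim_3c`` emits proximity-ligation (3C/Hi-C) read-pairs. The taxon of
  each pair follows the community abundance profile; the genomic separation
  of a cis pair is drawn from a truncated mixture of a geometric and a
  uniform distribution (the long-tailed decay observed in real libraries);
  the second end is anchored at the restriction cut site nearest the drawn
  separation. No sequencing error is simulated for 3C pairs.
* ``sim_wgs`` emits paired-end shotgun reads with normally distributed
  insert sizes at per-taxon coverage proportional to relative abundance.

Chromosomes are treated as flat, unfolded rings: coordinates, restriction
sites and read extraction all wrap around the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import AbundanceProfile, GenomeSet, codes_to_seq

__all__ = [
    "C3Params",
    "WGSParams",
    "ReadPairSet",
    "find_sites",
    "draw_cis_separation",
    "cis_separation_cdf",
    "fit_cis_mixture",
    "sim_3c",
    "sim_wgs",
    "wgs_pair_counts",
    "wgs_total_bases",
]


@dataclass(frozen=True)
class C3Params:
    """Proximity-ligation simulation parameters.

    ``cis_geom_p`` is the geometric success probability of the short-range
    decay (mean separation ~ 1/p); ``cis_uniform_weight`` is the mixture
    weight of the long-range uniform component. Defaults approximate a 3C
    library with a few-kilobase characteristic separation; the paper-style
    calibration against a measured separation histogram is available via
    :func:`fit_cis_mixture`.
    """

    read_len: int = 150
    enzyme_motif: str = "CATG"  # NlaIII
    cis_geom_p: float = 3e-4
    cis_uniform_weight: float = 0.1
    trans_prob: float = 0.1

    def __post_init__(self):
        if not (0 < self.cis_geom_p <= 1):
            raise ValueError("cis_geom_p must be in (0, 1]")
        if not (0 <= self.cis_uniform_weight <= 1):
            raise ValueError("cis_uniform_weight must be in [0, 1]")
        if not self.enzyme_motif or any(c not in "ACGT" for c in self.enzyme_motif):
            raise ValueError("enzyme motif must be a non-empty ACGT string")


@dataclass(frozen=True)
class WGSParams:
    """Shotgun paired-end simulation parameters (error-free by default)."""

    read_len: int = 150
    insert_mean: float = 450.0
    insert_sd: float = 100.0
    error_rate: float = 0.0

    def __post_init__(self):
        if min(self.read_len, self.insert_mean, self.insert_sd) <= 0:
            raise ValueError("read_len, insert_mean and insert_sd must be positive")


def find_sites(sequence: str | np.ndarray, motif: str) -> tuple[np.ndarray, np.ndarray]:
    """Forward-strand motif occurrences on a circular sequence.

    Returns 0-based motif start positions and the derived cut coordinates
    (position just past the motif, modulo sequence length). Sites spanning
    the origin are found; ``N`` in the sequence never matches.
    """
    if isinstance(sequence, np.ndarray):
        seq = codes_to_seq(sequence)
    else:
        seq = sequence.upper()
        if any(c not in "ACGTN" for c in set(seq)):
            raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    if any(c not in "ACGT" for c in motif):
        raise ValueError("motif must be over {A,C,G,T}")
    L, m = len(seq), len(motif)
    if m > L:
        raise ValueError("motif longer than sequence")
    doubled = seq + seq[:m - 1]
    starts = []
    i = doubled.find(motif)
    while i != -1:
        if i < L:
            starts.append(i)
        i = doubled.find(motif, i + 1)
    starts = np.array(sorted(starts), dtype=np.int64)
    cuts = (starts + m) % L
    return starts, cuts


def _trunc_geom_ppf(u: np.ndarray, p: float, t: int) -> np.ndarray:
    """Inverse CDF of a geometric(p) truncated to support {1..t}."""
    log_q = np.log1p(-p)
    z = -np.expm1(t * log_q)  # 1 - (1-p)^t
    k = np.ceil(np.log1p(-u * z) / log_q)
    return np.clip(k, 1, t).astype(np.int64)


def draw_cis_separation(params: C3Params, chrom_len: int,
                        rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw cis genomic separations from the truncated geometric/uniform mixture.

    Support is {1 .. chrom_len//2} (circular distance semantics): with
    probability ``cis_uniform_weight`` the separation is uniform, otherwise
    geometric(p) truncated and renormalized on the same support.
    """
    if chrom_len <= 2 * params.read_len:
        raise ValueError("chromosome too short for the configured read length")
    t = chrom_len // 2
    use_uniform = rng.random(size) < params.cis_uniform_weight
    out = np.empty(size, dtype=np.int64)
    n_uni = int(use_uniform.sum())
    if n_uni:
        out[use_uniform] = rng.integers(1, t + 1, size=n_uni)
    n_geo = size - n_uni
    if n_geo:
        out[~use_uniform] = _trunc_geom_ppf(rng.random(n_geo), params.cis_geom_p, t)
    return out


def cis_separation_cdf(params: C3Params, chrom_len: int, s: np.ndarray) -> np.ndarray:
    """Analytic CDF of the truncated mixture at separations ``s``."""
    t = chrom_len // 2
    s = np.asarray(s, dtype=float)
    k = np.clip(np.floor(s), 0, t)
    log_q = np.log1p(-params.cis_geom_p)
    z = -np.expm1(t * log_q)
    geo = -np.expm1(k * log_q) / z
    uni = k / t
    w = params.cis_uniform_weight
    return w * uni + (1 - w) * geo


def fit_cis_mixture(separations: np.ndarray, counts: np.ndarray, chrom_len: int,
                    read_len: int = 150) -> C3Params:
    """Fit (cis_geom_p, cis_uniform_weight) to a separation histogram by MLE."""
    from scipy.optimize import minimize

    t = chrom_len // 2
    s = np.asarray(separations, dtype=float)
    c = np.asarray(counts, dtype=float)

    def nll(x):
        logit_p, logit_w = x
        p = 1 / (1 + np.exp(-logit_p))
        w = 1 / (1 + np.exp(-logit_w))
        log_q = np.log1p(-p)
        z = -np.expm1(t * log_q)
        pmf = w / t + (1 - w) * p * np.exp((s - 1) * log_q) / z
        return -np.sum(c * np.log(np.maximum(pmf, 1e-300)))

    res = minimize(nll, x0=[np.log(1e-3), 0.0], method="Nelder-Mead")
    p = 1 / (1 + np.exp(-res.x[0]))
    w = 1 / (1 + np.exp(-res.x[1]))
    return C3Params(read_len=read_len, cis_geom_p=float(p), cis_uniform_weight=float(w))


@dataclass
class ReadPairSet:
    """Column-oriented container of simulated read-pairs with full truth.

    Coordinates are 0-based starts of each read on the circular source
    chromosome. ``pair_class`` is "cis", "trans" or "wgs". Sequences are
    optional (the fixture pipeline works from truth coordinates alone).
    """

    taxon_names: tuple[str, ...]
    taxon: np.ndarray          # index into taxon_names, per pair
    pos1: np.ndarray
    pos2: np.ndarray
    pair_class: str
    read_len: int
    seq1: np.ndarray | None = None  # (n, read_len) uint8 codes
    seq2: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.pos1)

    def taxon_of(self, i: int) -> str:
        return self.taxon_names[self.taxon[i]]

    def write_fasta(self, path, prefix: str = "rp") -> None:
        if self.seq1 is None:
            raise ValueError("read sequences were not emitted")
        with open(path, "w") as fh:
            for i in range(self.n):
                fh.write(f">{prefix}{i}/1\n{codes_to_seq(self.seq1[i])}\n")
                fh.write(f">{prefix}{i}/2\n{codes_to_seq(self.seq2[i])}\n")

    def write_fastq(self, path, prefix: str = "rp", quality: int = 40) -> None:
        if self.seq1 is None:
            raise ValueError("read sequences were not emitted")
        q = chr(quality + 33) * self.read_len
        with open(path, "w") as fh:
            for i in range(self.n):
                fh.write(f"@{prefix}{i}/1\n{codes_to_seq(self.seq1[i])}\n+\n{q}\n")
                fh.write(f"@{prefix}{i}/2\n{codes_to_seq(self.seq2[i])}\n+\n{q}\n")

    def write_truth_tsv(self, path, prefix: str = "rp") -> None:
        with open(path, "w") as fh:
            fh.write("read_id\ttaxon\tpos1\tpos2\tclass\n")
            for i in range(self.n):
                fh.write(f"{prefix}{i}\t{self.taxon_of(i)}\t{self.pos1[i]}"
                         f"\t{self.pos2[i]}\t{self.pair_class}\n")


def _extract_reads(genome: np.ndarray, pos: np.ndarray, read_len: int) -> np.ndarray:
    idx = (pos[:, None] + np.arange(read_len)[None, :]) % len(genome)
    return genome[idx]


def _nearest_cut(cuts: np.ndarray, target: np.ndarray, chrom_len: int) -> np.ndarray:
    """Cut coordinate circularly nearest to each target position."""
    j = np.searchsorted(cuts, target)
    right = cuts[j % len(cuts)]
    left = cuts[(j - 1) % len(cuts)]
    d_right = (right - target) % chrom_len
    d_left = (target - left) % chrom_len
    return np.where(d_right <= d_left, right, left)


def sim_3c(genomes: GenomeSet, profile: AbundanceProfile, n_pairs: int,
           params: C3Params, seed: int, emit_sequences: bool = True) -> ReadPairSet:
    """Simulate exactly ``n_pairs`` error-free 3C proximity-ligation read-pairs.

    The first end is placed uniformly on the source chromosome; the second
    end starts at the restriction cut site nearest the point one drawn
    separation away. Simulated genomes are monochromosomal, so no trans
    pairs are emitted.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cuts = {}
    for t in genomes.taxa:
        starts, cut = find_sites(genomes.sequences[t], params.enzyme_motif)
        if len(starts) < 2:
            raise ValueError(f"genome {t!r} has fewer than 2 restriction sites")
        cuts[t] = cut
    counts = rng.multinomial(n_pairs, profile.normalized)
    tax_col, p1_col, p2_col, s1_col, s2_col = [], [], [], [], []
    for ti, taxon in enumerate(genomes.taxa):
        n = int(counts[ti])
        if n == 0:
            continue
        g = genomes.sequences[taxon]
        L = len(g)
        pos1 = rng.integers(0, L, size=n)
        sep = draw_cis_separation(params, L, rng, size=n)
        sign = np.where(rng.random(n) < 0.5, 1, -1)
        target = (pos1 + sign * sep) % L
        pos2 = _nearest_cut(cuts[taxon], target, L)
        tax_col.append(np.full(n, ti))
        p1_col.append(pos1)
        p2_col.append(pos2)
        if emit_sequences:
            s1_col.append(_extract_reads(g, pos1, params.read_len))
            s2_col.append(_extract_reads(g, pos2, params.read_len))
    rp = ReadPairSet(
        genomes.taxa,
        np.concatenate(tax_col),
        np.concatenate(p1_col),
        np.concatenate(p2_col),
        "cis",
        params.read_len,
        np.concatenate(s1_col) if emit_sequences else None,
        np.concatenate(s2_col) if emit_sequences else None,
    )
    assert rp.n == n_pairs
    return rp


def wgs_pair_counts(genome_lens: dict[str, int], profile: AbundanceProfile,
                    xfold: float, read_len: int = 150) -> dict[str, int]:
    """Exact per-taxon pair counts: round(coverage * L / (2 * read_len)).

    Coverage of taxon i is ``xfold * q_i`` with q relative to the most
    abundant taxon (max q = 1).
    """
    out = {}
    for i, t in enumerate(profile.taxa):
        cov = xfold * profile.raw[i]
        out[t] = int(round(cov * genome_lens[t] / (2 * read_len)))
    return out


def wgs_total_bases(genome_lens: dict[str, int], profile: AbundanceProfile,
                    xfold: float, read_len: int = 150) -> int:
    """Total simulated bases for a WGS run (closed form, no generation)."""
    return sum(wgs_pair_counts(genome_lens, profile, xfold, read_len).values()) * 2 * read_len


def sim_wgs(genomes: GenomeSet, profile: AbundanceProfile, xfold: float,
            params: WGSParams, seed: int, emit_sequences: bool = True) -> ReadPairSet:
    """Simulate abundance-weighted paired-end shotgun reads.

    Insert sizes are Normal(insert_mean, insert_sd) truncated below at
    2 * read_len; read 2 is the reverse complement of the insert's far end.
    An optional uniform per-base substitution error can be applied.
    """
    if xfold <= 0:
        raise ValueError("xfold must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_per = wgs_pair_counts(genomes.lengths, profile, xfold, params.read_len)
    tax_col, p1_col, p2_col, s1_col, s2_col = [], [], [], [], []
    for ti, taxon in enumerate(genomes.taxa):
        n = n_per[taxon]
        if n == 0:
            continue
        g = genomes.sequences[taxon]
        L = len(g)
        inserts = rng.normal(params.insert_mean, params.insert_sd, size=n)
        lo = 2 * params.read_len
        for _ in range(100):
            bad = inserts < lo
            if not bad.any():
                break
            inserts[bad] = rng.normal(params.insert_mean, params.insert_sd, size=int(bad.sum()))
        inserts = np.maximum(inserts, lo).astype(np.int64)
        pos1 = rng.integers(0, L, size=n)
        pos2 = (pos1 + inserts - params.read_len) % L
        tax_col.append(np.full(n, ti))
        p1_col.append(pos1)
        p2_col.append(pos2)
        if emit_sequences:
            r1 = _extract_reads(g, pos1, params.read_len)
            r2 = 3 - _extract_reads(g, pos2, params.read_len)[:, ::-1]
            if params.error_rate > 0:
                for r in (r1, r2):
                    mask = rng.random(r.shape) < params.error_rate
                    r[mask] = (r[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
            s1_col.append(r1)
            s2_col.append(r2)
    if not tax_col:
        return ReadPairSet(genomes.taxa, np.empty(0, int), np.empty(0, int),
                           np.empty(0, int), "wgs", params.read_len,
                           np.empty((0, params.read_len), np.uint8) if emit_sequences else None,
                           np.empty((0, params.read_len), np.uint8) if emit_sequences else None)
    return ReadPairSet(
        genomes.taxa,
        np.concatenate(tax_col),
        np.concatenate(p1_col),
        np.concatenate(p2_col),
        "wgs",
        params.read_len,
        np.concatenate(s1_col) if emit_sequences else None,
        np.concatenate(s2_col) if emit_sequences else None,
    )
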