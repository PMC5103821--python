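"""Assembly and graph complexity diagnostics.

* ``n_eff`` — effective number of genomes in a community. Implemented as
  the order-1 Hill number 2^H of the normalized abundance profile, which is
  the unique normalization under which the mixing entropy below reaches
  exactly 1 when every contig's read proportions equal the community
  abundances; the simple sum of relative abundances is available behind
  ``method="sum_q"`` for compatibility.
* ``s_mixing`` — length-weighted mean per-contig entropy of read-source
  proportions, normalized by log2(N_eff): 0 when every contig is pure, 1
  when every contig is mixed in proportion to abundance.
* ``delta_s_mixing`` — forward finite difference of a mixing series over a
  divergence sweep.
* ``laplacian_entropy`` — Shannon entropy of the non-zero normalized-
  Laplacian eigenvalue spectrum (von Neumann-style graph entropy).
* ``n50_l50`` — standard assembly contiguity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .community import AbundanceProfile

__all__ = [
    "ContigSourceCounts",
    "n_eff",
    "s_mixing",
    "delta_s_mixing",
    "laplacian_entropy",
    "n50_l50",
]


@dataclass
class ContigSourceCounts:
    """Per-contig length and read counts per source genome."""

    contigs: tuple[str, ...]
    genomes: tuple[str, ...]
    lengths: np.ndarray           # (n_contigs,)
    counts: np.ndarray            # (n_contigs, n_genomes)

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.lengths <= 0).any():
            raise ValueError("contig lengths must be positive")
        if self.counts.shape != (len(self.contigs), len(self.genomes)):
            raise ValueError("counts shape mismatch")

    def proportions(self) -> np.ndarray:
        """p_ij, row-normalized; rows with zero reads stay all-zero."""
        tot = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot > 0, self.counts / np.maximum(tot, 1e-300), 0.0)
        return p

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tlength\t" + "\t".join(self.genomes) + "\n")
            for i, c in enumerate(self.contigs):
                row = "\t".join(str(int(x)) for x in self.counts[i])
                fh.write(f"{c}\t{int(self.lengths[i])}\t{row}\n")


def n_eff(profile: AbundanceProfile, method: str = "hill1") -> float:
    """Effective number of genomes of an abundance profile.

    ``hill1``: 2**H with H the Shannon entropy (bits) of the normalized
    abundances (equals the taxon count for a uniform profile). ``sum_q``:
    plain sum of the relative abundances (max-normalized).
    """
    if method == "sum_q":
        return float(np.sum(profile.raw))
    if method != "hill1":
        raise ValueError(f"unknown method {method!r}")
    p = profile.normalized
    p = p[p > 0]
    h = -np.sum(p * np.log2(p))
    return float(2.0 ** h)


def s_mixing(counts: ContigSourceCounts, profile: AbundanceProfile,
             neff_method: str = "hill1") -> float:
    """Assembly mixing entropy in [0, ~1].

    S = -1 / (L_asm * log2(N_eff)) * sum_j l_j * sum_i p_ij log2 p_ij,
    with 0*log(0) = 0. Undefined (error) for single-genome communities.
    """
    ne = n_eff(profile, neff_method)
    if ne <= 1.0 + 1e-12:
        raise ValueError("S_mixing undefined for an effectively single-genome community")
    p = counts.proportions()
    if not p.any():
        raise ValueError("no contig has any reads")
    with np.errstate(invalid="ignore", divide="ignore"):
        ent = np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
    l_asm = counts.lengths.sum()
    return float(-(counts.lengths * ent).sum() / (l_asm * np.log2(ne))) + 0.0


def delta_s_mixing(series: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Forward differences of (alpha_BL, S_mixing) samples.

    Returns one fewer point than the input: (alpha_k, (S_{k+1} - S_k) / h_k)
    with h_k the local step. The alphas must be strictly monotone.
    """
    if len(series) < 2:
        raise ValueError("need at least two samples")
    alphas = np.array([a for a, _ in series], dtype=float)
    s = np.array([v for _, v in series], dtype=float)
    h = np.diff(alphas)
    if (h == 0).any() or not ((h > 0).all() or (h < 0).all()):
        raise ValueError("alpha values must be strictly monotone and distinct")
    return [(float(a), float(d)) for a, d in zip(alphas[:-1], np.diff(s) / h)]


def laplacian_entropy(graph: nx.Graph, compat: bool = False, tol: float = 1e-9) -> float:
    """Entropy of the non-zero normalized-Laplacian eigenvalue spectrum.

    The normalized Laplacian N = D^{-1/2} (D - A) D^{-1/2} is computed on
    the nodes with positive degree. By default the non-zero eigenvalues are
    normalized to unit sum and the Shannon entropy -sum l~ log2 l~ is
    returned (non-negative; invariant under node relabeling and uniform
    edge-weight rescaling). ``compat=True`` evaluates the unnormalized
    literal sum l log2 l instead. Graphs without edges return 0.
    """
    active = [n for n, d in graph.degree(weight="weight") if d > 0]
    if not active:
        return 0.0
    sub = graph.subgraph(active)
    m = nx.normalized_laplacian_matrix(sub, weight="weight").toarray()
    lam = np.linalg.eigvalsh((m + m.T) / 2)
    lam = np.abs(lam[np.abs(lam) > tol])
    if lam.size == 0:
        return 0.0
    if compat:
        return float(np.sum(lam * np.log2(lam)))
    lam = lam / lam.sum()
    return float(-np.sum(lam * np.log2(lam))) + 0.0


def n50_l50(lengths) -> tuple[int, int]:
    """Assembly contiguity: L50 = fewest contigs holding half the total, N50 = their shortest."""
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if arr.size == 0 or (arr <= 0).any():
        raise ValueError("lengths must be non-empty and positive")
    cum = np.cumsum(arr)
    k = int(np.searchsorted(cum, cum[-1] / 2.0))  # first index with cum >= half
    if cum[k] < cum[-1] / 2.0:
        k += 1
    return int(arr[k]), int(k + 1)
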