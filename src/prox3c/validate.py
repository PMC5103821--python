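"""Gold-standard construction and weighted extended-Bcubed validation.

The gold standard maps each assembly contig to the set of community source
genomes it derives from, explicitly allowing one-to-many associations (a
conserved contig co-assembled from several closely related genomes belongs
to all of them). From contig-vs-reference alignments, a per-genome identity
mask over contig positions is filled in descending bitscore order
(first-writer-wins per position) and an association is accepted when the
positional mean identity mu_k exceeds 0.96 (strict).

Clustering solutions are scored against this overlapping truth with
weighted extended Bcubed: per-object multiplicity precision/recall,

    P*(oi, oj) = min(|K_i ∩ K_j|, |T_i ∩ T_j|) / |K_i ∩ K_j|
    R*(oi, oj) = min(|K_i ∩ K_j|, |T_i ∩ T_j|) / |T_i ∩ T_j|

(K = clusters, T = classes) are averaged per object with explicit object
weights (contig length in bp), then weight-averaged over objects, and F is
the harmonic mean. With uniform weights this reduces to conventional
extended Bcubed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "AlignmentRecord",
    "GoldStandard",
    "BcubedScores",
    "build_gold_standard",
    "multiplicity_pr",
    "weighted_bcubed",
    "read_alignments_tab",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment of a contig onto a reference genome.

    ``contig_start``/``contig_end`` are 0-based half-open on the contig;
    ``identity`` in [0, 1]; higher ``bitscore`` wins position occupancy.
    """

    contig: str
    genome: str
    contig_start: int
    contig_end: int
    identity: float
    bitscore: float


@dataclass
class GoldStandard:
    """contig -> non-empty set of source-genome (class) ids, plus weights."""

    classes: dict[str, frozenset]
    weights: dict[str, float]
    rejected: list[str] = field(default_factory=list)


def build_gold_standard(alignments: list[AlignmentRecord],
                        contig_lengths: Mapping[str, int],
                        mu_threshold: float = 0.96) -> GoldStandard:
    """Accept contig-genome associations whose masked mean identity mu_k > threshold.

    For each contig, alignments are traversed in descending bitscore; the
    first alignment to reach a (genome, position) cell sets its identity
    there. mu_k averages the mask over the whole contig length, so partial
    coverage dilutes identity. Contigs with no accepted association are
    reported in ``rejected``.
    """
    per_contig: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        if not (0 <= rec.contig_start < rec.contig_end <= contig_lengths[rec.contig]):
            raise ValueError(f"alignment interval outside contig {rec.contig!r}")
        per_contig.setdefault(rec.contig, []).append(rec)
    classes: dict[str, frozenset] = {}
    rejected: list[str] = []
    for contig in sorted(per_contig):
        length = contig_lengths[contig]
        recs = sorted(per_contig[contig],
                      key=lambda r: (-r.bitscore, r.genome, r.contig_start))
        masks: dict[str, np.ndarray] = {}
        filled: dict[str, np.ndarray] = {}
        for r in recs:
            mask = masks.setdefault(r.genome, np.zeros(length))
            occ = filled.setdefault(r.genome, np.zeros(length, dtype=bool))
            span = slice(r.contig_start, r.contig_end)
            free = ~occ[span]
            mask[span][free] = r.identity
            occ[span] = True
        accepted = frozenset(g for g, mask in masks.items()
                             if mask.mean() > mu_threshold)
        if accepted:
            classes[contig] = accepted
        else:
            rejected.append(contig)
    weights = {c: float(contig_lengths[c]) for c in classes}
    return GoldStandard(classes, weights, rejected)


def multiplicity_pr(oi, oj, clusters: Mapping, classes: Mapping) -> tuple[float, float]:
    """Multiplicity Bcubed precision and recall for an object pair.

    Requires the pair to share at least one cluster (for P*) and at least
    one class (for R*); calling it otherwise is a caller bug.
    """
    shared_k = len(clusters[oi] & clusters[oj])
    shared_t = len(classes[oi] & classes[oj])
    if shared_k == 0:
        raise ValueError("P* undefined: objects share no cluster")
    if shared_t == 0:
        raise ValueError("R* undefined: objects share no class")
    num = min(shared_k, shared_t)
    return num / shared_k, num / shared_t


@dataclass(frozen=True)
class BcubedScores:
    precision: float
    recall: float
    f: float
    n_objects: int
    n_dropped: int       # clustered objects absent from the gold standard
    n_unclustered: int   # gold objects not clustered, scored as singletons


def weighted_bcubed(clustering, gold: GoldStandard,
                    weights: Mapping[str, float] | None = None) -> BcubedScores:
    """Score an (overlapping) clustering against an overlapping gold standard.

    ``clustering`` is a list of node sets or a node -> set-of-cluster-ids
    mapping. Objects clustered but absent from the gold standard are
    dropped (counted); gold objects missing from the clustering are scored
    as singleton clusters (counted). Weights default to the gold standard's
    contig lengths.
    """
    if hasattr(clustering, "items"):
        memb = {o: set(ks) for o, ks in clustering.items()}
    else:
        memb = {}
        for i, c in enumerate(clustering):
            for o in c:
                memb.setdefault(o, set()).add(i)
    dropped = [o for o in memb if o not in gold.classes]
    for o in dropped:
        del memb[o]
    unclustered = [o for o in gold.classes if o not in memb]
    for i, o in enumerate(unclustered):
        memb[o] = {("__singleton__", i)}  # fresh label, type-agnostic
    objects = sorted(memb)
    if not objects:
        raise ValueError("no objects in common between clustering and gold standard")
    if weights is None:
        weights = gold.weights
    w = {o: float(weights[o]) for o in objects}
    classes = {o: gold.classes[o] for o in objects}

    by_cluster: dict[int, set] = {}
    by_class: dict = {}
    for o in objects:
        for k in memb[o]:
            by_cluster.setdefault(k, set()).add(o)
        for t in classes[o]:
            by_class.setdefault(t, set()).add(o)

    p_num = p_den = r_num = r_den = 0.0
    for oi in objects:
        d = set()
        for k in memb[oi]:
            d |= by_cluster[k]
        h = set()
        for t in classes[oi]:
            h |= by_class[t]
        sp = swp = sr = swr = 0.0
        for oj in d:
            shared_k = len(memb[oi] & memb[oj])
            shared_t = len(classes[oi] & classes[oj])
            sp += w[oj] * min(shared_k, shared_t) / shared_k
            swp += w[oj]
        for oj in h:
            shared_k = len(memb[oi] & memb[oj])
            shared_t = len(classes[oi] & classes[oj])
            sr += w[oj] * min(shared_k, shared_t) / shared_t
            swr += w[oj]
        p_num += w[oi] * sp / swp
        p_den += w[oi]
        r_num += w[oi] * sr / swr
        r_den += w[oi]
    p = p_num / p_den
    r = r_num / r_den
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return BcubedScores(p, r, f, len(objects), len(dropped), len(unclustered))


def read_alignments_tab(path, columns: Mapping[str, int] | None = None,
                        identity_percent: bool = True,
                        one_based_start: bool = True) -> list[AlignmentRecord]:
    """Ingest blast-tabular style alignments.

    The default column map follows blast outfmt 6 (qseqid sseqid pident ...
    qstart qend ... bitscore) with 1-based inclusive query coordinates;
    pass ``columns`` mapping field names {contig, genome, identity,
    contig_start, contig_end, bitscore} to 0-based column indices for other
    dialects (e.g. LAST tab converted layouts).
    """
    cols = {"contig": 0, "genome": 1, "identity": 2,
            "contig_start": 6, "contig_end": 7, "bitscore": 11}
    if columns:
        cols.update(columns)
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            ident = float(f[cols["identity"]])
            if identity_percent:
                ident /= 100.0
            start = int(f[cols["contig_start"]]) - (1 if one_based_start else 0)
            out.append(AlignmentRecord(
                f[cols["contig"]], f[cols["genome"]],
                start, int(f[cols["contig_end"]]),
                ident, float(f[cols["bitscore"]])))
    return out
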