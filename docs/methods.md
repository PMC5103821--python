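# Methods

This note documents the models implemented in `prox3c`, the parameter
defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical conventions adopted where the design was
genuinely open.

## Community evolution

A single circular ancestral chromosome is evolved down a rooted phylogeny.
Two four-taxon topologies are built in:

* **star** — all leaves at distance α_BL·ℓ from the root;
* **ladder** — an ultrametric caterpillar of height 1.5·α_BL·ℓ whose
  leaf-to-nearest-ancestor distances decrease in steps of ℓ/2
  (1.5ℓ, ℓ, 0.5ℓ, 0.5ℓ after scaling), so that taxon B's branch equals the
  star branch length and the community contains both closer and more
  distant relatives than the star at any α_BL. The exact assignment of the
  ℓ/2 increments to internal edges is this package's convention; other
  ultrametric realizations of the same verbal description exist.

Branch lengths are expected substitutions per site. Along a branch of
length *b* over a chromosome of length *L*:

* substitutions: Poisson(*b·L·sub_rate*), Jukes–Cantor (uniform choice
  among the three alternative bases). JC is the simplest defensible model
  and is exposed in `EvoParams` (`sub_rate`, default 1.0).
* indels, small HT insertions, large HT insertions, inversions: each class
  Poisson(*b·L·sub_rate·event_scale*) with `event_scale = 1e-4`. Sizes:
  indels geometric(mean 10 bp; the indel size scale is this package's
  choice — only the HT and inversion scales below are externally fixed),
  small HT Poisson(mean 200 bp), large HT uniform on 10–60 kbp, inversions
  geometric(mean 50 kbp).
* HT donor sequence is drawn from a random pool (independent uniform
  bases) and tagged distinctly in the lineage map; there is no model of a
  shared gene pool.

**Default ℓ = 0.08.** With the star tree, two leaves are separated by
2α_BL·ℓ substitutions/site, giving expected pairwise identity
1 − ¾(1 − e^{−(8/3)α_BL·ℓ}). At α_BL = 1 this is ≈0.85 (a community of
clearly distinct species, ~85% ANI) and at α_BL = 0.025 it is ≈0.996
(deep strain territory), spanning the operational 95%-ANI species boundary
roughly midway through the 10-point log grid on [0.025, 1]. An externally
supplied α_BL→ANI table can be attached for reporting; the package does
not recompute BLAST-based ANI.

**Circularity.** Chromosomes are flat unfolded rings for read simulation,
restriction-site finding and cis distances (all wrap the origin).
Structural-event breakpoints are drawn uniformly but events are placed so
they do not span the linearization origin; since a ring has no
distinguished origin, this is equivalent up to rotation for every
statistic the pipeline computes, and it keeps lineage intervals simple.

**Lineage map.** Every descendant base belongs to exactly one provenance
segment (ancestral interval + strand, HT donor, or de-novo indel) with an
identity fraction that is degraded multiplicatively as substitutions hit
the segment. Repeated hits at one site are counted again — a negligible
upward bias in divergence at the rates used. Pairwise identity between two
descendants over an ancestral window is approximated as the product of
their per-copy identities (independent divergence from the ancestor),
scaled by the smaller window coverage.

**Seeding.** One master seed; every stage derives child streams via
`numpy.random.SeedSequence(seed, spawn_key=...)` with fixed stage/branch
indices, so identical inputs and seed give byte-identical outputs.

## Read simulation

**3C pairs** are error-free (no base errors, no chimeric junctions, no
spurious inter-cellular ligations — see Limitations). The source taxon is
multinomial in the normalized abundance profile; end 1 is uniform on the
ring; the separation *s* is drawn from a mixture: with probability
`cis_uniform_weight` uniform on {1..⌊L/2⌋}, otherwise geometric(p)
truncated to the same support (exact inverse-CDF sampling, so the
empirical CDF converges to the analytic truncated mixture). End 2 starts
at the restriction cut site nearest to the point *s* away (either
direction); anchoring only the second end is this package's convention.
Defaults `cis_geom_p = 3e-4` (mean ≈ 3.3 kb separation) and
`cis_uniform_weight = 0.1` describe a plausible 3C library with a
few-kilobase characteristic range atop a long uniform tail; the mixture
can instead be fit to a measured separation histogram by maximum
likelihood (`fit_cis_mixture`). Simulated genomes are monochromosomal, so
the inter-chromosomal (trans) probability never engages.

**WGS pairs**: per-taxon coverage is `xfold × q_i` with q relative to the
most abundant taxon, pair count `round(cov·L/(2·read_len))`; inserts are
Normal(450, 100) truncated at 2·read_len; read 2 is reverse-complemented.
Error-free by default (`error_rate` adds uniform substitutions if wanted).
Four 3 Mbp genomes at uniform abundance and 10× depth give exactly
0.12 Gbp.

**Abundance profiles**: uniform, or decay by factors of 1/e
(1, 1/e, 1/e², 1/e³), max-normalized.

## 3C-contig graph

Nodes are all assembly contigs (isolated ones kept; clustering emits them
as singletons so validation sees every contig). A mapped pair is accepted
only with 100% per-read coverage and zero mismatches (relaxable policy for
real data); intra-contig pairs are ignored; edge weights are raw accepted
pair counts. No contact-map normalization is applied — raw counts carry
Poisson uncertainty that normalization functions only propagate — but
low-weight edge pruning (`prune_edges`) is available, which is the simple
defence against spurious-ligation noise when soft clustering real data.
SAM/BAM is ingested via pysam (secondary/supplementary alignments ignored
by default; non-unique placement is the user's mapper's concern); a plain
TSV dialect and an internal truth-coordinate mapper serve fixtures.

## Clustering

* **MCL**: canonical expansion/inflation loop on the column-stochastic
  adjacency with self-loops (weight 1, configurable), entry pruning at
  1e-5, convergence when the iterate changes by <1e-6. Clusters are the
  attractor systems of the limit matrix; the rare node attracted to
  several systems goes to the lexicographically first cluster, making the
  output a partition. Non-convergence raises with the last residual.
* **Louvain-hard**: the seeded `networkx` Louvain implementation, returning
  the final flat partition (no hierarchy) plus weighted modularity
  Q = Σ_c (W_c/W − (S_c/2W)²). "One step" is read as
  the full first-level-to-convergence partition rather than a single
  move-aggregate pass.
* **Louvain-soft**: after hard partitioning, for every inter-cluster edge
  (u,v) node u joins v's cluster and vice versa. Nothing else changes, so
  soft clusters are supersets of their hard counterparts and the operation
  is idempotent given the same hard input.
* **OClustR**: vertices ranked by relevance = mean(relative density,
  relative compactness), where relative density compares a vertex's degree
  to the largest degree in its closed neighborhood and compactness is the
  fraction of neighbors with no larger degree. Stars (vertex + neighbors)
  are selected greedily while uncovered vertices remain; stars whose every
  member is covered elsewhere are then removed, least relevant first. The
  similarity graph is the 3C-contig graph itself — no extra threshold and
  no runtime parameters. The refinement phase is a documented
  simplification of the original improvement heuristics; fixture tests pin
  its behavior.

## Gold standard and weighted extended Bcubed

From contig-vs-reference alignments, a per-genome identity mask over
contig positions is filled in descending bitscore order with
first-writer-wins occupancy (traversal order implies precedence; overwrite
semantics would let weaker alignments raise identity). μ_k is the mask
mean over the *contig* length — the denominator is read as contig length,
since averaging a contig's coverage over the whole genome length would
make μ_k ≈ 0 always — and associations require μ_k > 0.96 strictly.
Contigs with no accepted association are excluded and reported.

Scoring: per-object multiplicity precision/recall over the sets D(o) /
H(o) of objects sharing a cluster / class with o (both include o itself,
the standard convention), averaged with explicit per-object weights
(contig length), then weight-averaged over objects; F is the harmonic
mean. Objects clustered but absent from the gold standard are dropped
(counted in the report); gold objects left unclustered are scored as
singletons (counted). Uniform weights reduce the measure to conventional
extended Bcubed, which the tests verify against an independently coded
oracle.

## Complexity metrics

* **N_eff** is the order-1 Hill number 2^H of the normalized profile
  (H in bits). This is the unique normalization for which S_mixing below
  reaches exactly 1 when every contig's read proportions equal the
  community abundances, for *any* profile; it equals the taxon count for
  uniform profiles. The plain sum of max-normalized abundances is kept
  behind `method="sum_q"` for compatibility with other conventions.
* **S_mixing** = −(L_asm·log₂N_eff)^{-1} Σ_j l_j Σ_i p_ij log₂ p_ij with
  0·log 0 = 0; p_ij from truth-tagged reads (or WGS mappings on the
  external path). 0 for pure contigs, 1 at the fully mixed point; for
  skewed profiles with *uniformly* (rather than proportionally) mixed
  contigs it can exceed 1. Undefined for single-genome communities
  (explicit error). ΔS_mixing is the forward difference over the α_BL
  grid with the local step in the denominator.
* **H_L**: eigenvalues of N = D^{−1/2}(D−A)D^{−1/2} on positive-degree
  nodes (dense symmetric eigensolver; |λ| > 1e-9 counts as non-zero),
  normalized to unit sum, Shannon entropy in bits. This von Neumann-style
  normalization makes H_L non-negative and invariant under node
  relabeling and uniform weight rescaling (K_n gives log₂(n−1)); the
  unnormalized literal sum Σλ log₂λ is available via `compat=True`.
* **N50/L50**: standard definitions (sort descending, L50 = minimal count
  reaching half the total length, N50 = that contig's length).

## Synthetic co-assembly (fixture path)

Running a real assembler inside a benchmark loop is slow and
version-pinned, so the sweep's default path emulates the one property of
metagenome co-assembly that matters here: conserved sequence collapses
across strains. The ancestral coordinate space is fragmented
(Exponential(5 kb) pieces, 500 bp floor); within each fragment the
descendant copies are grouped by single linkage on truth pairwise
identity at threshold 0.96 (chosen to coincide with the gold-standard μ_k
rule, so "co-assembles" and "is a shared class" agree); each group is one
contig carrying all its taxa as classes. Taxon-specific insertions ride
along with their flanking contig. Reads are then placed by truth
coordinates; a read straddling a contig boundary is unmapped, mirroring
the strict coverage rule.

What this does *not* emulate: coverage-dependent fragmentation, assembly
errors and chimeras, k-mer-scale repeat collapse, or the gradual
contiguity collapse near the critical divergence region. Fixture results
therefore probe the clustering/validation machinery and the direction of
the divergence and depth responses, not absolute assembler-specific
scores. Pre-computed external assemblies, SAM mappings and alignment
tables can be substituted at the module boundaries for real-tool studies.

## Sweep

The default grid is 2 trees × 2 profiles × 10 α_BL values (log-spaced on
[0.025, 1]) × 3 WGS depths (10/50/100×) × 5 3C depths (10⁴–10⁶) = 600
combinations (40 communities, 120 read-sets), with MCL additionally swept
over 5 linear inflation values on [1.1, 2.0] (3000 clusterings).
Enumeration is deterministic in level order with per-run child seeds.
Execution is local and grid-agnostic; each result row embeds its seeds.

**Problem sizes.** The test and demonstration configurations run the
pipeline at 4 × 100 kb genomes with structural-event size distributions
scaled by the genome-length ratio (`scaled_evo_params`), 10³–10⁵ 3C pairs
— small enough to iterate on a laptop while preserving the qualitative
regimes: hard-clustering F_b³ collapses (via recall) once divergence falls
below the merge threshold, and Louvain-soft regains recall with 100× more
3C pairs. Full-scale (3 Mbp) runs use the same code paths.

## Known limitations

* No sequencing error, chimeric read-throughs, or spurious ligation noise
  in 3C simulation; noise robustness of Louvain-soft (which is sensitive
  to false inter-cluster edges) must be studied with edge pruning.
* SR-MCL is not implemented (its regularization schedule belongs to its
  own publication); the algorithm list is MCL, Louvain-hard, Louvain-soft,
  OClustR.
* The evolver is intentionally minimal: no selection, no codon structure,
  no gene gain/loss model beyond uniform HT insertions, single replicon.
* μ_k mask building assumes alignments in contig coordinates; no attempt
  is made to reconcile conflicting strand or split alignments.
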