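# prox3c

Simulation and benchmarking toolkit for metagenomic chromosome-conformation-capture
(3C/Hi-C) deconvolution.

## The problem

Metagenomic assembly scatters each community member's genome across many
contigs, and when closely related strains (>95% average nucleotide identity)
coexist in a sample, their conserved core genome co-assembles into *shared*
contigs. Proximity-ligation sequencing (3C/Hi-C) supplies a cell-of-origin
signal: read-pairs preferentially link loci that were spatially close inside
one cell, so counting 3C read-pairs between contigs yields a weighted
**3C-contig graph** whose community structure mirrors the genomes in the
sample. Deconvolution then becomes graph clustering — but a hard partition
cannot represent a shared contig that genuinely belongs to several strains;
that requires *soft* (overlapping) clustering, and evaluating overlapping
solutions requires an overlap-aware score.

`prox3c` provides the full benchmarking loop for this problem, for method
developers and experimental designers who want to know how divergence,
abundance skew, and sequencing depth affect strain resolution:

1. **Community simulation** — star or ladder phylogenies of four taxa with
   branch lengths scaled by a divergence factor α_BL; a circular ancestral
   chromosome is evolved with Jukes–Cantor substitutions, indels,
   horizontal-transfer insertions and inversions, with every descendant
   base tracked back to its source (the lineage map).
2. **Read simulation** — abundance-weighted WGS paired-end reads, and
   error-free 3C read-pairs whose cis separation follows a truncated
   geometric + uniform mixture with the second end anchored at the nearest
   restriction cut site (NlaIII `CATG` by default).
3. **Graph construction** — strict mapping acceptance (100% read coverage,
   zero mismatches), raw pair counts as edge weights, optional low-weight
   edge pruning.
4. **Clustering** — MCL (inflation-controlled), flat Louvain
   (modularity-maximizing), a naive Louvain-soft overlap extension (both
   endpoints of every inter-cluster edge join each other's cluster), and
   the parameter-free OClustR star-covering algorithm.
5. **Validation** — an overlap-aware gold standard (alignment identity-mask
   with the μ_k > 0.96 acceptance rule, or simulator truth), scored with
   **weighted extended Bcubed**:

   F_b³ = 2⟨P⟩⟨R⟩ / (⟨P⟩ + ⟨R⟩),

   where ⟨P⟩ and ⟨R⟩ are contig-length-weighted means of per-object
   multiplicity precision/recall
   P\*(o_i,o_j) = min(|K_i∩K_j|, |Θ_i∩Θ_j|) / |K_i∩K_j| (and R\* with the
   class intersection in the denominator). With uniform weights this is
   conventional extended Bcubed.
6. **Complexity metrics** — effective genome number N_eff, the assembly
   mixing entropy S_mixing (0 = pure contigs, 1 = contigs mixed in
   proportion to abundance), its forward difference over the α_BL sweep,
   normalized-Laplacian spectral graph entropy H_L, and N50/L50.

## Worked example

A scaled-down community (four 100 kb genomes, star tree, uniform abundance)
at two divergence extremes:

```python
from prox3c.sweep import RunSpec, SweepConfig, run_pipeline

cfg = SweepConfig(ancestor_len=100_000)
for alpha in (1.0, 0.025):
    for algo in ("louvain-hard", "louvain-soft"):
        row = run_pipeline(RunSpec(0, "star", "uniform", alpha, 100, 10_000, 42),
                           cfg, algorithms=(algo,))[0]
        print(f"alpha={alpha:<6} {algo:<13} F={row['f_b3']:.3f} "
              f"P={row['p_b3']:.3f} R={row['r_b3']:.3f} S_mix={row['s_mixing']:.2f}")
```

prints

```
alpha=1.0    louvain-hard  F=1.000 P=1.000 R=1.000 S_mix=0.00
alpha=1.0    louvain-soft  F=1.000 P=1.000 R=1.000 S_mix=0.00
alpha=0.025  louvain-hard  F=0.151 P=1.000 R=0.082 S_mix=1.00
alpha=0.025  louvain-soft  F=1.000 P=1.000 R=1.000 S_mix=1.00
```

At α_BL = 1 (≈85% pairwise identity) every contig is pure (S_mixing = 0)
and all algorithms recover the four genomes perfectly. At α_BL = 0.025
(≈99.5% identity, deep strain territory) nearly every contig is shared by
all four taxa (S_mixing ≈ 1): the hard partition can place each shared
contig in only one cluster, collapsing recall, while the soft extension
recovers the overlapping memberships.

The same pipeline is scriptable from the shell
(`prox3c simulate | graph | cluster | validate | metrics | sweep`); see
`prox3c --help`.

## Layout

```
src/prox3c/
  community.py   phylogenies, abundance profiles, genome evolver + lineage truth
  readsim.py     restriction sites, cis-separation model, 3C and WGS simulators
  graph.py       mapping acceptance, 3C-contig graph build / prune / summary
  cluster.py     MCL, Louvain-hard/-soft, OClustR, weighted modularity
  validate.py    identity-mask gold standard, weighted extended Bcubed
  metrics.py     N_eff, S_mixing, ΔS_mixing, Laplacian entropy, N50/L50
  sweep.py       grid enumeration, synthetic co-assembly, end-to-end pipeline
  cli.py         command-line entry points
docs/methods.md  model details, parameter choices, limitations
```
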