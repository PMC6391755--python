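# Methods

## Problem and model

Hi-C proximity ligation joins DNA fragments that were crosslinked in the
same cell.  For a metagenome this means intra-genome contacts dominate:
read pairs linking two contigs of the same organism occur roughly an
order of magnitude more often than inter-cellular (noise) pairs.  `hicbin`
models the assembly as a weighted undirected graph over contigs, with the
weight of an edge the bias-corrected Hi-C interaction strength, and reads
genome bins off as the flow modules of that graph.

### Contact map

Counting is per read pair: one usable pair increments *c<sub>ij</sub>* by
one (and *c<sub>ji</sub>*, symmetrically), whatever its insert size or
intra-contig separation; both mates on one contig increment the diagonal
*c<sub>ii</sub>*.  A pair is usable when both mates are mapped, primary
and non-supplementary (the `samtools -F 0x904` contract) with MAPQ at or
above `min_mapq` (default 60, appropriate for BWA-MEM `-5SP` mapping of
Hi-C reads).  Mates are matched by query-name adjacency, so input must be
name-sorted; coordinate-sorted input is rejected with instructions rather
than silently dropping every pair.

Two acceptance filters follow.  Contigs shorter than `min_len` (default
1000 bp) are excluded before accumulation: short contigs carry weak,
high-variance signal that damages normalization.  Contigs with fewer than
`min_signal` (default 5) *non-self* observations are then removed
iteratively until a fixed point, because removing one weak contig can
strand a neighbour below threshold; the fixed point makes the
conservation invariant (retained + length-excluded + signal-excluded =
input pairs) exact.  Self-counts never contribute to the signal test.
Duplicate pairs are kept by default (an optional flag removes
coordinate-identical duplicates), since the upstream pipeline may or may
not have deduplicated.

### Bias removal

Raw counts are biased by restriction-site density, mappability and
accessibility.  Stage one divides *c<sub>ij</sub>* by
max(*n<sub>i</sub>*, 1) · max(*n<sub>j</sub>*, 1), where *n<sub>i</sub>*
tallies recognition-site occurrences over all library enzymes.  Site
tallies count occurrences of the recognition sequence or its reverse
complement at distinct start positions (identical for the palindromic
GATC and AATT); the floor of 1 keeps site-free contigs analyzable, and
only relative factors matter downstream.  Stage two balances the result
bistochastically: Knight–Ruiz inexact Newton iteration (conjugate-gradient
inner loop, cone line searches) until every structurally non-zero row of
diag(*x*)·*A*·diag(*x*) sums to 1 within `tol` (default 1e−6,
`max_iter` 1000 matrix–vector products).  If Newton stalls — possible on
very sparse or nearly reducible support — the implementation falls back
to symmetric Sinkhorn–Knopp scaling (*x* ← *x*/√rowsum) and reports which
method converged.  All-zero rows take scale 1; rows with no off-diagonal
support are dropped before balancing since they cannot carry edges.  The
stopping contract is deliberately pinned to the row-sum tolerance, not to
any particular inner-iteration schedule.

### Clustering

The balanced matrix becomes the wc-graph: one edge per off-diagonal
non-zero, diagonals exported as self-links (kept by default; removable
with a flag since their effect on flow clustering is a judgment call).
Partitions minimize the two-level map equation for undirected weighted
walks — node visit rates proportional to strength, module exit rates to
boundary weight.  The backend is igraph's Infomap with `trials` (default
10) restarts under a single seeded RNG; an independent
`map_equation_codelength` function lets any partition be scored without
the backend, and exhaustive-search tests hold the backend to the true
optimum on small graphs.  Bin labels are a pure function of the
partition: descending contig count, ties by descending extent, then
smallest member id — so identical inputs and seed give byte-identical
output.  Bins under `min_extent` (default 50 kbp, under half the
shortest known bacterial genome) are dropped from the FASTA/report
output.  The default seed (9878132) is logged on every run.

### Validation

Ground truth from contig-vs-reference alignments (tabular, BLAST-6 or
MAF dialects): per contig and reference, aligned query intervals are
unioned and the reference becomes a source label when coverage reaches
`min_cov_frac` (default 0.5; the threshold is explicit rather than
claimed to match any prior convention).  Truth is *soft* — a contig may
carry several labels where genomes share sequence — weighted by contig
length.

Two extrinsic scores are provided.  AMI (hard): multi-label items are
resolved by a uniform seeded draw; the normalizer is max(H<sub>t</sub>,
H<sub>p</sub>), matching the historical scikit-learn default the metric
is calibrated against (other normalizers selectable).  Weighted B³
(soft): pair precision min(|C∩C′|, |T∩T′|)/|C∩C′| averaged with item
weights over pairs sharing a predicted bin (self included), recall with
C and T swapped, F the harmonic mean.  With unit weights and hard truth
this is classical B³.  Because predictions are hard, items with
overlapping truth cap both scores below 1 — an inherent gap, not an
error.  Recall is reported both over clustered items only and over all
truth items (unclustered mass as zero recall); the latter is the
community-wide completeness figure and is the monotone quantity under
depth changes.

MAG rank classifiers consume externally estimated completeness and
contamination (marker-gene estimation is out of scope).  The simple
standard ranks the axes independently (near ≥90 / substantial ≥70 /
moderate ≥50 / partial; low ≤5 / medium ≤10 / high ≤15 / very high).
The MIMAG draft ranks are high (>90, <5, rRNA+tRNA present), medium
(≥50, <10), else low; an unknown rRNA/tRNA flag caps the rank at medium.

## Synthetic communities

The simulator's defaults are the study conditions of the package's tests:
10 genomes of 0.5–1 Mbp, GC evenly spaced over 0.30–0.70 (so every draw
covers the extremes), 2×10⁵ Hi-C pairs, noise fraction 0.1, fragment mean
10 kbp, seed 9878132.  All randomness flows from the one seed through a
spawned `SeedSequence` per stage.

**Abundances** are i.i.d. generalized-Pareto draws.  The profile is
calibrated to the long-tailed, roughly 50:1 most-to-least spread reported
for gut-scale communities of ~63 members, which corresponds to shape
ξ = −2 at scale 31 (location 0) in the standard ξ-parametrization; with
10 genomes the realized spread is typically 5–150:1, occasionally leaving
the rarest member too shallow to bin — which is the realistic regime, and
why community-wide recall grows with Hi-C depth.

**Genomes** are i.i.d. base sequences at the target GC, treated as
circular.  The expected spacing between recognition-site starts is then
analytic — 1/p with p the product of per-base probabilities — and the
empirical site density of generated genomes matches it to binomial
precision; this is also the calculation behind the two-enzyme library
recommendation (an AT-rich four-cutter site expects one site per 61 bp
at 28.3% GC but one per 3396 bp at 73.8%).

**Pairs** condition on restriction sites, as real proximity ligation
does.  Each pair picks a genome by abundance; with probability
`noise_frac` the partner is a uniform cut site of an independently drawn
(abundance-weighted) genome — inter-cellular noise, so the realized
inter-genome fraction is `noise_frac` × (1 − Σ aᵢ²).  Otherwise the pair
is intra-genome: one end uniform on the genome's pooled cut sites, and
the partner either at a circular exponential separation (mean
`decay_mean`, default 20 kbp) snapped to the nearest cut site, or — with
probability `bg_frac`, default 0.5 — uniform over the genome's sites.
The uniform component models the cell-wide crosslinking background that
makes a whole replicon one flow module; with a purely local kernel the
clustering correctly-but-unhelpfully resolves a circular genome into
arc-shaped sub-modules, which is a property of 1-D lattices under the
map equation, not of real Hi-C data.  Pairs are emitted both as a truth-
labelled table and as an idealized name-grouped SAM (error-free 75 bp
alignments, MAPQ 60) so the production ingestion path is exercised.

**Fragmentation** cuts each circular genome at uniform breakpoints into
pieces of mean `frag_mean`, merging pieces under 500 bp into a
neighbour; fragment lengths sum to the genome length exactly, giving a
hard, total truth labelling.

What the simulator does *not* emulate: sequencing error and read-level
artefacts, assembly chimerism and co-assembly of similar strains,
insert-size structure, GC-coverage bias, and ANI-controlled strain
mixtures.  Passing end-to-end tests therefore demonstrates the
correctness and stability of the map–normalize–cluster–score machinery
under realistic signal/noise geometry, not robustness to assembly
pathology; on real data the soft-truth machinery and the contig-splitting
helper exist precisely because those pathologies appear.

## Numerical and design notes

- Problem sizes in the test suite are chosen for a single CPU: the
  default community (~7.5 Mbp, ~750 contigs, 2×10⁵ pairs) runs the whole
  pipeline in a few seconds; balancing is verified on dense random
  matrices to 500×500; exhaustive map-equation search is limited to
  graphs of ≤ 12 nodes (full partition enumeration to n = 8,
  bipartitions beyond).
- GC is computed over unambiguous bases only; all-N sequences report 0.
- Depth comes from SPAdes-style `cov_` header tokens or an external
  table, never from Hi-C coverage (which the method itself shows is
  biased).
- `split_contigs` emits k = max(1, round(L/target)) pieces differing by
  ≤ 1 bp, so concatenation is the identity; piece ids append `.k`.
- Balancing is scale-invariant and unique on strictly positive matrices,
  which is what permits the Sinkhorn fallback to stand in for Newton
  without changing the answer.
- Known limitations: no multi-level clustering output, no strain
  splitting, no assembly-graph awareness, no windowed (sub-contig) maps
  or heatmap plotting; degenerate (IUPAC) recognition sites and
  methylation sensitivity are out of scope.
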