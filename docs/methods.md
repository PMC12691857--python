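# Methods

This note records the models implemented in `cnmnet`, the parameter choices
that matter, what the synthetic generators do and do not emulate, and the
numerical decisions taken where the design was genuinely open.

## Co-expression arm

### Preprocessing

Raw counts are filtered to genes with more than `min_count` (default 10)
reads in at least `ceil(min_fraction × n_samples)` samples (default 90%).
Normalization uses median-of-ratios size factors: per gene, the geometric
mean across samples (genes containing any zero are excluded from the
reference set); per sample, the median of count/geomean ratios. When no gene
is all-nonzero the code falls back to library-size factors scaled to
geometric mean 1, with a warning. Correlation work happens on
`log2(normalized + 1)`. An optional batch correction mean-centers each gene
within each cohort and restores the global gene mean; it is a deliberate
lightweight stand-in for full empirical-Bayes batch modelling and is
adequate for location (not scale or interaction) batch effects.

### Network and modules

The adjacency is unsigned, `a_ij = |cor|^β`. Unsigned was chosen because the
module-level biology of interest mixes up- and down-regulated processes;
with an unsigned network, anti-correlated genes driven by one process land
in one module. The default β = 12 matches the multi-cohort transcriptome
setting; co-expression layers exported for the multilayer network use the
per-omics presets (transcriptomic β = 10, TOM > 0.15; proteomic β = 12,
TOM > 0.25; metabolomic β = 5, TOM > 0.05). The export threshold is applied
to TOM values (the thresholded quantity is ambiguous in principle between
raw adjacency and TOM; TOM was chosen because it is the matrix actually
computed immediately before export, and the choice is documented here so it
can be revisited). A scale-free-fit diagnostic across candidate powers is
provided (`pick_soft_threshold`) but the pipeline always takes an explicit
power.

Module detection approximates dynamic tree cut: average-linkage clustering
of `1 − TOM`, a *static* cut at absolute height 0.99 → **0.95** (see below),
initial modules = clusters of ≥ `min_module_size` (default 30), then a
rescue pass assigning leftover genes to the module whose eigengene they
correlate with at r > 0.5, else grey. Two numbers differ from the obvious
defaults and were set by analysing the merge-height distribution of planted
data:

* **Cut height 0.95.** On the 1−TOM scale, unrelated genes merge in a tight
  band just below 1.0 while genuine branches complete far lower. A cut
  placed relative to the height *distribution* (e.g. a quantile) lands
  inside the noise band whenever noise merges outnumber the cut's tail, and
  collapses the forest into one tree; an absolute 0.95 separates branch
  completion (≤ ~0.9 under moderate noise) from the noise band robustly.
* **Rescue threshold 0.5.** At n = 24 samples the null distribution of a
  Pearson correlation has standard deviation ≈ 0.21, so a rescue threshold
  of 0.3 admits roughly 8% of unrelated genes per module; 0.5 is ≈ 2.4 null
  standard deviations and keeps the background grey without losing true
  members (which correlate with their eigengene at r ≈ 0.9).

Modules whose eigengenes are closer than `merge_threshold` (default 0.25) in
correlation dissimilarity are merged iteratively, eigengenes recomputed
after every merge, until no pair qualifies; the loop terminates because the
module count strictly decreases. Final labels are color names ordered by
module size, with grey reserved for unassigned genes.

### Eigengenes and trait statistics

A module eigengene is the first right singular vector of the per-gene
z-scored module submatrix, unit norm, sign-aligned with the module's mean
profile. Module–trait association is a Pearson correlation over
pairwise-complete samples with `t = r·sqrt((n−2)/(1−r²))`, two-sided p from
the Student t distribution with n−2 df, and Bonferroni correction over the
number of traits. Traits are group-averaged (every animal carries its
experimental group's mean), which reduces the effective resolution of the
test; the permutation-null calibration below shows the raw p-value remains
accurate under that granularity. Classification: a module is *beneficial*
if it has at least one significant (adjusted p < 0.05) positive correlation
among {normalized TA mass, relative maximal force, hanging time} and/or a
significant negative one among {% central nuclei, % abnormal mitochondria,
% small fibers}, with no significant correlation of the opposite pattern;
*pathogenic* is the mirror image; anything else, including conflicting
evidence, is unclassified.

## Multilayer network and random walk

A network is a set of multiplexes (layers over one node type) plus
bipartites between multiplex pairs. Edges live in 2–3 column TSV files;
undirected edges are canonicalized (sorted endpoints), duplicates collapse
to the maximum weight, self-loops are dropped, unweighted edges carry weight
1. Reported density uses `m / (n(n−1)/2)` for every layer row, directed
ones included — the single convention that reproduces the published summary
rows that can be checked arithmetically; bipartite density is left blank
because the printed node count sums both sides and the split is unknown.

The walk runs on supra-states (multiplex, layer, node). From state
(k, α, i): choose uniformly among {stay in k} ∪ {multiplexes where i has a
bipartite neighbor, respecting bipartite direction} — this reallocates
unreachable jump mass to staying and keeps columns stochastic without
inventing teleportation; staying picks a layer of k uniformly (including α)
and follows an out-edge of i proportionally to weight; jumping moves to a
bipartite neighbor proportionally to bipartite weight and lands in a
uniformly chosen layer. Mass with nowhere to go (no out-edge in the chosen
layer, or a fully isolated state) is *dangling* and redirected to the
restart vector, the standard PageRank correction. The restart vector puts
uniform mass on the seeded multiplexes (renormalized when some multiplexes
carry no seed), splits it across a multiplex's seeds by seed weight, and
across layers uniformly. Per-node scores are sums of supra-scores over
layers — summation, not max, because it preserves total probability.

The iterative solver is a power iteration
`s ← (1−r)(M s + (d·s) v) + r v`, a contraction with factor (1−r), run to
L1 tolerance 1e−10 (default r = 0.7 converges in ~20 iterations). A dense
linear solve of the same fixed point serves as the verification oracle on
small instances, and the single-multiplex single-layer case is additionally
checked against an independently written personalized PageRank. Rankings
sort by score descending with ties broken by node id, so results are
bit-reproducible.

## Hub resampling null

Network propagation favours topologically central nodes regardless of the
seed (water, ATP, cations, mitochondrial and ribosomal genes in the real
data). The null: draw `n_iterations` (default 1000) single-gene seeds
uniformly *with replacement* from the seed pool (with replacement so the
iteration count may exceed the pool), run the walk, and count per category
how often each node enters the top 10/50/100. A node is a nonspecific hub
when its top-50 count exceeds 5% of converged iterations — strictly
exceeds, so a count at exactly the boundary is not called. Hub calling (and
removal) applies to gene and metabolite categories; phenotype occurrences
are counted but never removed. Each iteration's seed is excluded from its
own ranking: a seed trivially tops its own list and would contaminate the
null (this exclusion is a documented choice; including the seed would
inflate every pool member's count by its own draws). The paired
full-vs-subset scan reruns the identical seed sequence on a copy of the
network with chosen layers dropped (nodes retained as isolated) and reports
paired counts and their Pearson correlation per category and level.

## Joint-seed queries and overlap

A disease query seeds the walk with a gene and a phenotype term jointly in
one run (restart mass ½/½ across the two multiplexes under the uniform
default), returning the top-20 genes and metabolites with seeds excluded.
Across several queries, the union of top lists is partitioned exactly into
shared-by-all, shared-by-some (with the sharing labels), and query-specific
nodes.

## Synthetic study conditions

The generators define the conditions under which the pipeline's claims are
tested; they return ground truth and are bit-reproducible per seed.

**Expression.** Four groups (WT, disease, WT-treated, disease-treated) × 6
animals. Three planted 50-gene modules, each a latent factor (standard
normal per sample plus group-mean shifts) entering gene log-means with
effect 1 and gene-level noise sd 0.3; 250 background genes; negative
binomial counts (dispersion 0.05, library factors uniform in [0.7, 1.4],
baselines log-uniform over [100, 1000] mean counts). Three deliberate
choices: (a) the background majority exists because size factors are medians
over genes — in a toy where most genes carry planted factors, normalization
absorbs the factors themselves, an artifact absent from real transcriptomes;
(b) dispersion 0.05 (typical for inbred-mouse bulk RNA-seq) keeps the count
layer's noise below the stated gene-level noise, so "noise sd 0.3" remains
the operative condition; (c) the three group-shift axes (healthy-muscle,
disease-severity, treatment-response) are only mildly collinear — exactly
mirrored axes would make two factors correlate at |r| ≈ 0.6, which an
*unsigned* network cannot separate even in principle. Traits are
ρ-correlated transforms of their linked factor, then replaced by group
means (reproducing the group-level phenotyping granularity); the achieved
correlation after averaging is reported and warned about when it falls far
from the target, which is expected — group averaging discards within-group
signal by design.

**Metabolites.** Log-normal abundances with planted co-abundance blocks,
sized for the metabolomic layer presets.

**Networks.** Erdős–Rényi, preferential-attachment ("pa", Barabási–Albert
matched to the ER edge count, labels shuffled), child→parent random DAG, and
edgeless layer kinds; random bipartites; planted hubs wired to a stated
fraction of their multiplex in every layer. `table_shaped_network_spec`
mirrors the real composition (5 gene layers, 2 metabolite layers, directed
reactions, phenotype DAG, isolated tissues, 8 bipartites) at reduced scale.

**Hub-scan scale.** The hub acceptance check runs on a 2000-gene multiplex
with three preferential-attachment layers of mean degree ~10 and a planted
hub wired to 50% of genes, 200 iterations per scan. Two scale effects
dictated this: homogeneous (ER) degrees make the top-50 rotate with seed
neighborhoods so nearly every node clears 5% — heavy-tailed layers, like
real interactomes, create the stable elite the hub rule presupposes; and at
1000 nodes the *average* top-50 occupancy is exactly the 5% cutoff
(50/1000), putting typical nodes on the boundary by construction, whereas at
2000 nodes average occupancy is 2.5% and a median-degree node stays well
below the rule (≤ 9/200 across 30 validation replicates) while the planted
hub is called in every replicate.

**What the generators do not emulate.** Real cohort structure (batch
confounding beyond location shifts, varying sequencing depth regimes, gene
length effects), signed regulatory relationships, ontology semantics,
reaction stoichiometry, and database noise/bias. Passing recovery tests on
these conditions shows the machinery is correct and calibrated at the
stated noise levels; it does not certify biological findings on any real
dataset, and module counts/sizes on real cohorts will differ from the toy's.

## Degenerate inputs and numerical choices

Zero-variance genes get zero correlation (with a warning); constant traits
yield rows with missing statistics rather than errors; |r| = 1 maps to
p = 0; empty top-k requests return all rows with a warning; unknown removal
targets warn and are skipped (removal is idempotent); networks left with a
zero-layer multiplex by layer-dropping are a configuration error. Solver
tolerances: RWR L1 1e−10 (iteration cap 1000, non-convergence raises with
the residual); oracle agreement asserted at 1e−8; brute-force agreement of
the co-expression math at 1e−12.

## Problem sizes

Default test and acceptance problem sizes — 450-gene expression matrices,
≤200-supra-state oracle toys, 2000-gene hub scans of 200 iterations ×
20 replicates, a ≤200-node-per-multiplex full-pipeline run — were chosen so
the whole suite completes in a few minutes on one CPU while keeping every
statistical regime (sample sizes, noise levels, top-k fractions) in the
range where the corresponding claim is meaningful.

## Known limitations

* The dynamic-tree-cut approximation is a flat static cut plus eigengene
  rescue; it does not reproduce branch-shape-sensitive splits of the full
  hybrid algorithm on deeply nested dendrograms.
* Median-of-ratios + log2(x+1) is not a variance-stabilizing transform;
  low-count genes retain higher variance than a VST would give them.
* The walk's uniform factorization matches the stated "uniform"
  probabilities but other factorizations (e.g. jump-first-then-layer with
  different tie handling) are defensible; the oracle tests pin down this
  implementation, not the uniqueness of the choice.
* Bipartite weights influence jumps only; no within-bipartite normalization
  across multiple bipartites linking the same multiplex pair beyond summing
  their neighbor lists.
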