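# Methods

## Model

The package clusters aligned nucleotide sequences under a
Dirichlet-process mixture of multinomials — the no-admixture model of
population structure.  A partition of the *n* sequences into *K*
clusters of sizes *n_1..n_K* has prior probability

    f(p, K | α, n) = α^K ∏ Γ(n_i) / ∏_{i=1}^{n} (α + i − 1),

the Ewens/CRP partition distribution with concentration α.  Within a
cluster, the allele counts *n_jl* at each variable locus *j* are
multinomial with Dirichlet(β_j)-distributed frequencies, giving the
closed-form marginal likelihood

    p(D_k | H1) = ∏_j  Γ(Σ_l β_jl) / Γ(Σ_l (β_jl + n_jl)) · ∏_l Γ(β_jl + n_jl)/Γ(β_jl).

Loci are treated as independent (no linkage), alleles as unordered
categories; sequences enter only through their per-locus allele
counts.

## Inference

Exact posterior inference over partitions is intractable, so the
package uses Bayesian hierarchical clustering: agglomerative merging
where the merge criterion is the posterior probability r_k of the
"one cluster" hypothesis against the alternative consistent with the
current subtrees.  The recursions per internal node k with children i, j:

    d_k  = α Γ(n_k) + d_i d_j          (leaves: d = α)
    π_k  = α Γ(n_k) / d_k
    p(D_k|T_k) = π_k p(D_k|H1) + (1 − π_k) p(D_i|T_i) p(D_j|T_j)
    r_k  = π_k p(D_k|H1) / p(D_k|T_k)

The final partition cuts the tree top-down, keeping every subtree
whose r_k ≥ 0.5 (leaves are always kept whole).

Rather than starting from singletons, a fast Ward pre-clustering of
the pairwise SNP mismatch matrix is cut into K_init small initial
clusters (default min(⌈n/4⌉, 100) — the pre-clustering only needs to
over-partition, so any K_init comfortably above the expected K works).
Initial clusters are atomic: their internal merge prior is fixed at
π = 1, so a leaf's tree marginal equals its H1 marginal and its
d-value is α regardless of member count.  This keeps π above the
leaves a function of the merge structure alone and preserves the
factorial dominance that makes α nearly irrelevant.  For more than
10 000 samples (configurable) the quadratic distance matrix is
replaced by Ward clustering of the first 50 principal components of
the one-hot allele matrix; the randomized SVD seed is fixed (42) for
reproducibility.

### Numerical notes

Everything runs in natural-log space.  Both mixture weights are taken
directly from the d-recursion: log π_k = log αΓ(n_k) − log d_k and
log (1−π_k) = log d_i + log d_j − log d_k.  The second identity
matters: computing log(1−π) from log π underflows catastrophically
once the factorial dominates (π = 1 − ε with ε below double
resolution of log π), which would silently delete the "keep separate"
hypothesis and collapse every dataset to one cluster.  r_k is
computed as log π + log p(D|H1) − log p(D|T), clamped at 0.

Greedy selection maximizes log r; ties break toward the
lexicographically smallest pair of original leaf indices.  After a
merge only the new node's pairwise values are computed, so the
agglomeration costs O(loci · K_init²).  Cluster count vectors are
summed from the children, never recomputed from samples.  Ward
linkage and tree cutting use scipy's deterministic implementations;
tie handling inside the linkage follows scipy's nearest-neighbour
chain order.

## Priors and hyperparameter selection

Three Dirichlet prior families are supported, each multiplied by a
scalar scale c:

- **baps** (default): β_jl = 1/N_A(j), non-informative per locus;
- **symmetric**: β_jl = 1;
- **bhc_counts**: β_jl proportional to the global allele counts,
  normalised so each locus's hyperparameters sum to N_A(j), making
  its magnitude comparable to the symmetric prior.

The "optimized" variants choose c by empirical Bayes: the root node
marginal p(D|T) of the singleton-leaf Ward hierarchy approximates the
model evidence for a given prior, and a golden-section search over
log10 c ∈ [−2, 2] (tolerance 10⁻³ log10 units; both configurable)
maximizes it.  The search also evaluates c = 1 and returns the best
point seen, so an optimized prior is never worse than the unscaled
one on the optimization hierarchy.  α is fixed at 1: the π recursion
is dominated by Γ(n_k), and the tests verify that varying α across
two orders of magnitude leaves the clustering essentially unchanged.

## Conditioning on a pre-computed tree

Given a rooted Newick tree over the same labels, one post-order pass
computes the node statistics with singleton leaves (each count vector
formed by a single addition of its children's), and the same r ≥ 0.5
top-down cut returns a partition whose clusters are clades of the
input tree, in time linear in the node count.  Multifurcations are
binarized as a left-to-right ladder before the recursion; the cut
only decides at original nodes.  Branch lengths are ignored — the
model sees topology and alleles only.  Trees with a multifurcating
root are treated as unrooted and rejected unless midpoint rooting is
requested explicitly; edges without lengths count as length 1 for the
midpoint only.

## Missing data and site filtering

A column is a variable site if at least two distinct A/C/G/T bases
occur among its non-missing characters.  Gaps, N and IUPAC ambiguity
codes contribute no allele count anywhere (they are not fractionally
distributed); a monomorphic column with missing data is dropped.  The
sparse encoding stores only non-majority-allele carriage plus a
missingness mask, with majority ties broken alphabetically.

## Bootstrap

Cluster stability is assessed by resampling the retained variable
loci with replacement (the same number as retained), rerunning the
full pipeline — including prior-scale optimization when configured —
and summing binary co-clustering matrices.  The accumulated matrix is
invariant to cluster label switching and its dimension does not
depend on each replicate's K.  Default 100 replicates; a replicate
with no usable variation is redrawn (bounded retries).

## Synthetic data generator

The generator emulates the statistical structure the model assumes
rather than a genealogical process: K demes, biallelic loci, per-deme
allele frequencies drawn Dirichlet(γ·1) around a global draw, and
i.i.d. categorical genotypes.  γ defaults to 0.5 (Jeffreys prior for
a biallelic frequency), giving the U-shaped site-frequency spectra
typical of SNP panels; `mixing ∈ [0, 1]` blends deme frequencies
toward the global mean as a migration analogue (0 = fully
differentiated, 1 = no structure).  Because genotypes are i.i.d.
across loci and samples, the generator produces no linkage
disequilibrium, no shared genealogy within demes, and no
recombination-rate variation — passing tests therefore demonstrate
correct inference under the model's own assumptions, not robustness
to the genealogical correlations of real sequence data.

## Evaluation

The Fowlkes–Mallows index FM = √(TP/(TP+FP) · TP/(TP+FN)) compares an
inferred partition with the simulated truth via pair counts.  Edge
conventions where the formula is 0/0: two all-singleton partitions
score 1 (they are identical); TP = 0 with any disagreeing pairs
scores 0.  Against a phylogeny without ground truth, the consistency
error is the fraction of within-cluster pairs whose MRCA clade
contains a leaf from another cluster, which penalizes
over-clustering quadratically in cluster size.

## Problem sizes used in the checks

The simulation-based tests and the acceptance script run 5, 10 and 25
demes at 20 samples per deme with 200 biallelic loci (mixing 0, and a
mixing sweep over {0, 0.3, 0.6, 0.9} at 10 demes), the
tree-conditioning checks use 2–5 demes of 8 samples at 100–150 loci,
and the bootstrap check uses two fully differentiated 10-sample demes
over 40 loci with 50 replicates.  These sizes exercise every code
path (including the K_init cap and both initial-clustering routes)
while keeping the whole suite fast on a single CPU.

## Known limitations

- Linkage between loci is ignored; strongly recombining or clonal
  data can be over- or under-partitioned relative to genealogical
  expectations.
- The agglomeration is greedy: it returns a local optimum of the
  r-criterion, not the global MAP partition.
- Initial clusters are never split, so errors in the Ward
  pre-clustering at very low differentiation propagate.
- The sub-quadratic genie-style linkage backend is not implemented;
  the PCA + Ward route is the large-n path.
- Single-level clustering only; no nested/hierarchical lineage
  levels and no admixture.
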