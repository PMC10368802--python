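# Methods

## The problem

Graph-based clustering of scRNA-seq data (Leiden and friends) operates on a
nearest-neighbour graph, not on the expression measurements themselves, so
nothing guarantees that two clusters it reports are transcriptionally
distinct. In practice analysts over- or under-cluster and then merge by eye.
codemerge replaces that manual step with a statistical one: clusters are
deliberately over-split upstream, every cluster pair is tested for
significant transcriptional difference on per-cell enrichment scores, and
mutually non-significant pairs are merged.

## Code-scoring

Let Θ be the T × F cells × genes log-normalized expression matrix, C the
set of tentative clusters, and G_i the marker gene set of cluster i
(selected by one-vs-rest Welch t-tests, keeping up to `max_genes = 5`
upregulated genes with BH-adjusted p < 0.05). A gene is *expressed* in a
cell when its stored value is strictly positive; this single threshold is
shared by every module.

For cell κ and cluster i the co-expression machinery uses three
quantities:

* H(κ, S) — the number of genes of set S expressed in κ;
* P(κ, G_i) — the empirical joint probability of co-expressing G_i at κ's
  levels: the product over g ∈ G_i of (#cells with expression ≥ Θ_{κ,g})/T.
  Ties are counted inclusively and the cell itself always counts, so each
  factor lies in [1/T, 1] and the log below is finite;
* f(S) — the winsorized minimum intersection count: |S| for |S| ≤ 2,
  otherwise |S| − 1 ("all genes but one").

The **coexpr-score** is

    Ψ_{κ,i} = log2( H(κ, G_i) / P(κ, G_i) )   if H(κ, G_i) ≥ f(G_i), else 0.

The **code-score** Ω additionally requires that κ co-expresses *none* of
cluster i's negative gene sets:

    N_i = { G_j − G_i : j ≠ i, |G_j ∩ G_i| ≥ f(G_i), G_j − G_i ≠ ∅ },

i.e. when another cluster's markers overlap G_i almost completely, the
genes that distinguish it become veto sets for i. A negative set N_ij is
*co-expressed* when H(κ, N_ij) strictly exceeds f(N_ij): singleton and
two-gene sets can never veto, and larger sets must be expressed in full.
We deliberately use this strict rule as the default (the winsorized
variant, H ≥ f, is available as `negative_rule="winsorized_ge"`). The
reason is empirical and structural: in over-clustered data, sub-clusters
of one population select nearly identical marker sets that differ in a
single weak gene; under the ≥ rule each such difference becomes a
one-gene veto that is satisfied by a large fraction of the very cells the
cluster is made of. At the full design scale of the bundled simulation
this collapses the mean own-cluster positive-score fraction from ~0.92 to
~0.40, drags pair-test AUROC below 0.99 and makes cluster-merge collapse
the eight true groups to two; the strict rule reproduces the intended
behaviour (AUROC ≈ 1.0, correct recovery). Wherever Ω is nonzero it
equals Ψ exactly — masking only zeroes.

Two control scorers are included for benchmarking: `additive` (mean
expression of G_i in the cell minus the matrix-wide mean of G_i — the
classic additive gene-set score, which goes positive when *any* marker is
expressed) and `additive_neg` (the same with negative-set masking). They
exist to exhibit the cross-scoring failure mode; parity with any external
tool's exact scorer is out of scope.

## Cluster-merge

For a candidate pair (i, j), four score vectors are formed: Ω_{i∼i},
Ω_{j∼i} (column i restricted to cells of i and of j) and Ω_{i∼j}, Ω_{j∼j}.
Each vector is summarized to k = 15 values before testing — by default its
k evenly spaced quantiles (probabilities 0, 1/(k−1), …, 1, linear
interpolation, so min and max are always included). Summarization is the
pseudobulking idea applied to scores: treating thousands of cells as
independent observations makes t-tests wildly anti-conservative.
Alternatives: `k_bins` (means within k equal-probability bins, empty bins
dropped), `k_means` (1-D k-means centroids, deterministically seeded from
the quantile summary so runs are reproducible), and `none` (per-cell
testing, kept for diagnostics and for demonstrating the pathology it
causes).

Two two-sided Welch t-tests give p_i (column i between the two cell
groups) and p_j (column j). Welch rather than Student because equal
variances cannot be assumed between a cluster scoring for itself and a
cluster scoring across. If both summarized vectors are constant the test
is degenerate: p = 1 when the means agree, 0 otherwise. All 2·|pairs|
raw p-values from one testing round form a single BH family; a pair is
significantly different when either adjusted p-value falls below
`p_cut = 0.01` (strict <). Pairs that are *not* significantly different
define edges of a graph over clusters; connected components are merged
(transitivity is forced — a cell can carry only one label — and is part of
the behavioural contract). New labels are "0", "1", … by decreasing
component cell count, ties broken by the lexicographically smallest member
label; when nothing merges, input labels are kept untouched.

Marker selection, scoring and merging can be iterated; one iteration is
the default, matching the observation that the procedure converges almost
immediately on real data. With many clusters, pair testing can be
restricted to mutual nearest neighbours (`pair_selection="mnn"`,
`mnn_neighbours = 4`) in the space of cluster score profiles Ξ, where
Ξ_{ij} is the mean cluster-j score among cells of cluster i; with
neighbourhood size |C|−1 this reduces to all-pairs testing. Size-1
clusters cannot be tested (no variance) and are pre-merged into the
nearest cluster by Euclidean profile distance, with a warning.

## The synthetic data generator

The simulator emulates the scenario the method targets: populations
defined by *combinations* of genes rather than single markers. Base counts
come from an explicit hierarchical model — per-gene mean ~ Gamma(shape
0.3, scale 2), per-cell library factor ~ LogNormal(0, 0.35), counts ~
negative binomial with dispersion 0.1 (variance μ + 0.1 μ²), drawn as a
Gamma–Poisson mixture. These defaults give overdispersed, zero-rich
matrices with realistic library-size spread; they are configuration, not
estimates from any dataset. Defaults: 10,000 genes × 3,000 cells, 8
groups assigned uniformly at random, a shared pool of 15 DE genes, each
group marked by a unique random combination of 3–7 pool genes.

DE injection, per (group, gene): a proportion τ ~ N(0.85, 0.05) (clamped
to [0,1]) of the group's zero-count cells is set to the gene's median
non-zero count (computed from the unmodified base matrix, across all
cells), then the group's counts for that gene are multiplied by
φ ~ N(6, 1) (clamped below at 1, one draw per group-gene) and rounded.
Genes outside the pool are bit-identical to the base counts. Everything is
deterministic under the seed.

What the generator does **not** emulate: batch effects, logistic dropout
curves, trajectories/doublets, and any dataset-specific parameter fit.
Tests passing on it show that the method recovers combinatorially defined
populations under strong, clean effects; they do not certify behaviour on
noisy real data with ambient RNA or continuous gradients.

Benchmark protocol utilities mirror the evaluation design: every cluster
with more than 20 cells is split into 3 random near-equal subgroups
(smaller clusters stay intact), pairs of subgroups are labelled
significantly different iff their parents differ, and clusters can be
downsampled to at most 15 cells each. Pair discrimination is measured by
sweeping the significance cutoff over {0} ∪ {2^-c : c = 0..100}, calling a
pair significant when min(p_i, p_j) < cutoff (the continuous analogue of
the either-direction call), and integrating TPR vs FPR by trapezoid with
(0,0)/(1,1) anchors. AUROC raw p-values are swept; BH is monotone on a
fixed family so the curve is unchanged. Cell-abundance bias is the
Spearman correlation between −log10(min p) (floored at 1e-300) and
log2(n_i + n_j).

## Numerical and design choices

* BH adjustment is implemented once (step-up, monotonicity enforced from
  the largest rank down, capped at 1) and shared by marker selection
  (adjusted across all genes within each one-vs-rest comparison) and pair
  testing (one pooled family per iteration).
* Welch statistics for marker selection are computed from per-cluster
  sums/sums-of-squares accumulated by a sparse one-hot product, so the
  expression matrix is never copied per cluster; zero pooled variance
  yields t = 0, p = 1.
* Marker ranking ties break deterministically: ranking statistic
  descending, the other statistic descending, gene id ascending. When
  fewer than `min_genes` genes pass the filters, the top-ranked
  upregulated genes are taken regardless of the filters and a warning is
  recorded — cluster-merge needs a non-empty marker set for every cluster.
  A cluster with no upregulated gene at all is an error.
* Identical negative sets arising from different j are stored once; this
  cannot change whether a cell is vetoed.
* A code-score of exactly 0 means "filtered or vetoed" and is not
  distinguished from the measure-zero case H/P = 1.
* Duplicate gene/cell identifiers on input are disambiguated in file
  order (x, x-1, x-2, …). MTX directories are transposed to cells × genes
  by default, matching the common genes × cells convention of pipeline
  output.
* Normalization scales each cell's total to the median per-cell total and
  applies log1p; zero-total cells are rejected by name, zeros are
  preserved exactly and per-cell order is preserved.

## Known limitations

* When two groups' true combinations share all but one or two genes, the
  top-5 marker sets of their sub-clusters may lose the discriminating
  genes; the pair's adjusted p-values can then land just above p_cut and
  transitive merging chains the groups. On the bundled generator this
  shows as occasional under-recovery (7 instead of 8 groups on some
  seeds) even while pair-ranking AUROC stays at 1.0. Raising `max_genes`
  or `p_cut` resolves specific cases; both are exposed.
* On a *pure-null* population split into clusters of very unequal sizes,
  quantile summarization keeps the false-positive rate at adjusted
  p < 0.01 essentially zero while per-cell testing calls large fractions
  of null pairs significant. The abundance-bias *correlation*, however,
  behaves differently than on real data: marker selection overfits small
  clusters more, and with n fixed at k summaries that effect-size
  gradient appears as a negative correlation between p and pair size,
  whereas per-cell tests largely cancel it against n-driven power. The
  correlation diagnostic is therefore informative on over-clustered data
  with genuine signal, not on a pure null.
* The additive control scorer is intentionally minimal (no
  expression-binned background gene sampling); it is a benchmarking foil,
  not a replacement for any published scorer.
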