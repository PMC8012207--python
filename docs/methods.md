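# Methods

`protomap` re-implements, as a tested library, a batch-aware single-cell
RNA-seq analysis workflow for early developmental tissue: quality control,
batch-median depth normalization, variable-gene selection with
batch-regressed scaling, PCA with a permutation test for the number of
informative components, clustering on a Jaccard-weighted k-nearest-neighbor
graph with Louvain community detection, iterative subclustering with
rule-based removal of contaminating populations, dendrogram merging of
subclusters into major populations, Wilcoxon marker detection with gene
scores, cross-dataset cluster correspondence, and loess pathway
trajectories over developmental stage. A synthetic-data generator with
known ground truth stands in for primary tissue data throughout the test
suite.

## Quality control

Cells are kept when they have at least `min_genes_per_cell` detected genes
(default 500) and a mitochondrial count fraction of at most
`max_mito_fraction` (default 0.10). Both boundaries are inclusive on the
keep side: "fewer than 500" and "greater than 10%" are read strictly, so a
cell at exactly 500 genes or exactly 10% mitochondrial content is retained.
Mitochondrial genes are recognized by a configurable gene-name prefix
(default `MT-`); no gene-level filtering is performed. The velocity input
filter keeps cells with total counts >= 200, spliced counts >= 20 and
unspliced counts >= 10 (all inclusive) and requires spliced/unspliced
layers.

## Normalization

Batches (days of capture) are normalized independently: each cell's counts
are scaled so its total equals the median raw total of its batch, after
which batches are concatenated. This is the algebraic composition of the
two-step description "scale each cell to the batch maximum, then multiply
by the batch median" — both intermediate factors are recorded in the
provenance so the reading is auditable. The median uses the midpoint of the
two central values for even batch sizes; a single-cell batch normalizes to
its own total. Expression is then transformed as `log2(x + 1)`; the unit
pseudocount keeps zeros at zero and preserves sparsity.

## Dimensionality reduction

Variable genes are selected Seurat-v2 style: per gene, the exp-scale mean
`m = mean(2**x - 1)` and dispersion `var/mean` are computed; genes are
placed into 20 equal-frequency bins by mean, dispersions are z-scored
within bins (a zero-variance bin yields z = 0 for its members), and genes
with z >= 0.5 and `ln(1 + m)` inside [0.0125, 3] are kept, ordered by z.
The mean window is applied on the `ln(1+mean)` axis — the convention under
which those default cutoffs were established; applied to the raw exp-scale
mean they would exclude essentially every informative gene at realistic
sequencing depth.

Scaling regresses batch out per gene by least squares on batch indicator
variables (equivalently, centering on batch means; a single batch reduces
to plain centering), standardizes residuals to unit variance (genes with
zero residual variance are set to 0) and clips at ±10. PCA is exact (full
SVD) with a deterministic sign convention: each component's
largest-magnitude loading is positive.

The number of informative components is chosen by permutation parallel
analysis: each gene's values are permuted across cells independently (100
permutations by default), the leading covariance eigenvalues are recomputed,
and the count of leading observed eigenvalues exceeding the permutation 95%
quantile (componentwise) is returned, floored at 2. On pure-noise matrices
the count is almost always 2; five planted factors with total signal sd 5x
the noise sd are recovered reliably. The original study cites an external
calculation for this step that is not restated in its methods; permutation
parallel analysis is this package's substitute and is flagged as such.

## Clustering

The k = 10 nearest neighbors of each cell (Euclidean, in the significant-PC
space, self excluded, distance ties broken toward the lower cell index)
define the graph's candidate edges: the symmetrized kNN pairs. Each edge
(i, j) is weighted by the Jaccard similarity of the two neighbor sets,
|N(i) ∩ N(j)| / |N(i) ∪ N(j)|, and zero-weight edges are dropped. All-pairs
Jaccard would be O(n²) and adds no candidate edges that survive the
zero-weight drop in practice; the symmetrized-kNN candidate set is the
default. Community detection is an in-house Louvain: local moves (each node
re-inserted where the modularity gain is largest, ties toward the lower
community id, with a fresh singleton community as fallback when every
existing community is worse) in seeded shuffled visit order, then
aggregation, iterated to convergence. Convergence is followed by a
node-level refinement pass on the original graph (alternating with fresh
aggregated hierarchies until no single-node move improves), and — on small
graphs, where rounds are cheap (budget 4096/n, capped at 60) — by seeded
iterated local search: a random third of the nodes are reassigned and the
partition re-optimized, keeping improvements. The best of 5 seeded restarts
is returned together with a per-pass modularity log (nondecreasing by
construction). Modularity is the weighted Newman–Girvan form with a
resolution parameter (default 1.0). On exhaustive sets of weighted graphs
with up to 8 nodes the returned partitions reach the enumeration optimum.

A known property of this (and any) modularity-based clustering: large
homogeneous populations are subdivided. At ~800+ cells per type the
within-type kNN subgraphs are large enough that splitting them raises
modularity — independent implementations (python-igraph) return the same
split — so top-level Louvain over-partitions, exactly as the original
workflow's 63 top-level clusters and 54 subclusters reflect. The intended
remedy is the merge step below; recovery of planted types at the Louvain
level is only expected for populations up to a few hundred cells.

Subclustering restricts to the cells of selected clusters, reruns
normalize → reduce → cluster, annotates the subclusters against exclusion
marker panels (e.g. neuronal programs) and removes matching subclusters,
iterating until none match (error after 10 iterations). Merging builds the
clusters × genes gene-score matrix, computes Pearson correlations between
cluster rows, agglomerates with average linkage on distance 1 − r and cuts
the tree to the target number of populations (default 9).

## Markers and annotation

Markers are called one-vs-rest per cluster with the Wilcoxon rank-sum test
(clusters under 3 cells are skipped). Genes are pre-filtered on detection
fraction (frac_in >= 0.1) and log2 fold enrichment (>= 0.25, difference of
mean log2 expression in vs out). P-values use the exact null distribution
for small tie-free samples and the tie-corrected normal approximation
otherwise ("auto"), and are Benjamini–Hochberg adjusted across tested genes
within each cluster. The gene score integrates specificity and fold
enrichment as

    gene_score = log2FC * frac_in / max(frac_out, 0.01)

with the frac_out floor preventing division blow-up for perfectly specific
markers. The formula is pluggable (`score_fn`); a difference-based
specificity (frac_in − frac_out) can be substituted. The exact formula of
the workflow this follows is published separately and was not restated; the
ratio form is this package's operationalization.

Annotation is rule-based: marker panels name required and forbidden genes
with a minimum gene score (all required genes must pass, or any with
`match_any`). Panels are evaluated in precedence order — specific
populations (mesenchymal/LUM, IPC, neuron, endothelial, microglia,
pericyte) before the generic progenitor panel, since the mesenchymal-like
population also expresses strong progenitor markers (SOX2, VIM). A cluster
passing the progenitor panel is labeled radial glia when the neurogenic
panel (NES/HES5, any-match) also passes and neuroepithelial otherwise;
unmatched clusters are "unknown". Default panels ship as an editable YAML
file; the neurogenic gene list in particular is a configuration choice, not
a claim about the canonical list.

## Cross-dataset correspondence

Each dataset's clusters are represented by gene-score vectors over the
union of both datasets' marker genes (zero where a gene is not a marker of
a cluster), mapped through an ortholog table when gene namespaces differ
(identity by default). Cluster-to-cluster Pearson correlations over that
shared universe form the correspondence matrix; calls are `r >= threshold`
with a default threshold of 0.4, always recorded in the output metadata
because the original analysis does not state its numeric value.
Zero-variance rows yield r = 0 with a warning. The fidelity summary reduces
the matrix to one value per shared cell type — the maximum correlation
among same-type cluster pairs — and averages these for the overall figure;
types present on one side only are reported as missing and excluded.

## Trajectories

A program score is the per-cell mean log2 expression over a gene set's
present genes (missing genes are counted and logged; an empty intersection
is an error). Stage labels map to consecutive integers in sorted order
unless an explicit numeric mapping is supplied. The trajectory is a
degree-1 loess (tricube kernel over the `ceil(span * n)` nearest points,
span 0.75 by default) evaluated on a 100-point grid spanning the observed
stages only. The confidence band is pointwise-normal:
`smooth + z_q * sigma * ||l(x)||`, where `l(x)` are the linear smoother
weights at x and `sigma` is estimated from residuals at the observed stage
positions; the default quantiles (0.05, 0.95) give the 5–95% band. Local
linear fitting is exact on linear data, which the tests exploit as a
closed-form limit.

## Synthetic data

The generator emulates the data structure the pipeline assumes. Counts are
`Poisson(s_i * b_g,batch(i) * lambda_g,type(i))`, where `s_i` is a
lognormal library-size factor (default log-mean ln 3000 in the reference
configurations, log-sd 0.35), `b` a per-gene lognormal batch factor with
unit mean (log-sd 0.15 by default), and `lambda` the cell-type program: a
flat baseline rate with marker genes boosted multiplicatively (default 8x,
40 markers per type in the reference configuration of 2,000 genes). The
first `mito_gene_count` genes are named `MT-…` and their rates are set so
the expected mitochondrial count share equals the type's
`mito_fraction_mean` (default 0.05). Gradient cells draw a uniform position
u and interpolate the two endpoint programs linearly, labeled by the
nearest endpoint; per-stage abundance weights control composition (e.g. a
stage-restricted mesenchymal-like population). Spliced counts are binomial
thinning of totals (default fraction 0.75), so spliced + unspliced equals
the total exactly. Structure (type/stage/batch assignment) and noise
(factors and counts) use separate RNG streams derived from the seed.

Paired datasets reuse the programs of shared types with per-gene lognormal
perturbation (log-sd = divergence) and replace non-shared types with novel
random programs, recording the planted correspondence.

What the generator does not emulate: gene-gene correlation within programs,
doublets, ambient RNA, UMI saturation, or realistic gene-level mean
variation (baselines are flat within a type). Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not performance claims about real tissue. Poisson-lognormal rather
than negative binomial keeps the parameter count small while still giving
overdispersed marginals; NB overdispersion would be a config extension.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale data chosen to exercise
every code path: 5,000 cells / 6 types for pipeline recovery, 5,400 cells /
54 subclusters for merge recovery, 1,500 cells per dataset for paired
correspondence (10 seeds), 500x200 matrices for the significant-PC
calibration (40 seeds), and exhaustive enumeration oracles on graphs of at
most 8 nodes and rank-sum samples of at most 8 values. Tolerances: 1e-9 on
modularity against enumeration, 1e-10 on exact p-values, 1e-8 relative on
the normalization contract, 1e-6 on the loess linear limit. Degenerate
inputs (zero-total cells, single-cell batches, zero-variance genes or
cluster profiles, clusters under 3 cells) are either defined explicitly
above or raise a validation error naming the offending field.

## Known limitations

- Top-level Louvain subdivides large homogeneous populations (see
  Clustering); interpret cluster counts jointly with the merge step.
- The significant-PC rule, gene-score formula and fidelity statistic follow
  this package's stated operationalizations of steps whose original
  definitions live in external publications.
- The correspondence threshold (0.4) and loess span (0.75) are
  conventional defaults, not fitted values.
- The synthetic generator's simplifications above bound what the green
  test suite can certify about primary tissue data.
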