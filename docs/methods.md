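# Methods

This note documents the statistical machinery behind `refanno`, the
defaults it ships with, the design choices made where reasonable
alternatives existed, and what the simulation-based test suite does and
does not demonstrate.

## Normalization and contrasts

All expression contrasts operate on log2(CP10K + 1): counts per 10,000
per column (pseudo-bulk profile) or per cell, log-transformed with a
pseudocount of 1. Pseudo-bulk profiles aggregate member cells by
*summation*; since every downstream contrast is depth-normalized, sum
versus mean aggregation differs only by a per-column scale factor that
normalization removes.

**Moderated one-vs-rest t.** Pseudo-bulk differential expression has one
column per cell type and no replicates, so the per-gene contrast fits
log values of the target + contrast columns on [intercept, target
indicator] by OLS and shrinks gene-wise residual variances toward their
median with 4 pseudo-observations (empirical-Bayes style; the prior
degrees of freedom add to the residual df in the t reference
distribution). P-values are one-sided (up-regulation) and BH-adjusted
within the tested candidate set. With exactly two columns no p-value
exists; the operation falls back to log-fold-change ranking and flags
the result. Thresholds: p < 0.05 for the within-reference contrast,
p < 0.001 for the atlas contrast, both with positive effect. (These are
"significantly up-regulated" filters; the strict atlas level reflects
that the atlas contrast is the specificity filter of the marker
pipeline.)

**Unwanted-variation adjustment.** Reference and atlas profile matrices
come from different sources, so before the atlas contrast the shared
gene space is adjusted: empirical control genes (least-variable 10%
of shared genes after depth normalization) are factor-analyzed by SVD of
their centered log values, and the top k = 2 right singular vectors act
as per-column unwanted-factor scores. Each gene's loading on those
factors is then estimated *excluding the column being tested* and the
fitted contribution removed. The leave-target-out step matters: with a
global residualization, a genuine marker elevation in the tested column
leaks into its own adjustment and is partially removed, biasing the
contrast toward the null. Estimating the loading from the remaining
columns removes gene-level batch offsets (visible in the other columns
of the same source) without touching the tested effect. k = 0 disables
the adjustment; k, the control fraction and all thresholds are config
keys.

**Round-2 markers.** At single-cell resolution the label-vs-rest and
label-vs-negative-control contrasts use a one-sided Wilcoxon rank-sum
test (exact when both groups are ≤ 25 cells and tie-free, tie-corrected
normal approximation with continuity correction otherwise), requiring
fold change > 1.5 on depth-normalized means with pseudocount 1 and
Bonferroni-adjusted p < 0.05 across all genes.

## Similarity metrics

Round 1 uses Kendall's tau-b (tie-corrected; scRNA-seq vectors are
tie-heavy), computed over the reference's top-N variable genes
(default N = 2000) intersected with the query gene space. Rank
correlation is invariant to strictly monotone per-cell transformations,
which is what makes the candidate step robust to library-size and
capture-efficiency distortion. Ties between reference types are broken
by lexicographic type name for determinism. Variable genes are ranked by
standardized variance against a binned mean-variance trend (20 bins)
when the profile has ≥ 10 columns; with fewer columns the trend fit
degenerates and plain log-CP10K variance is used.

Round 2 uses the exact multinomial log-probability of the cell's counts
under each label's profile-derived probability vector (profile column on
the round-2 gene set, +1 pseudocount per gene, renormalized — the
pseudocount keeps the support strictly positive). The round-2 gene set
is the top-2000 variable genes of the local reference profile,
mirroring the round-1 feature logic; with a single surviving label the
label's expressed genes are used.

## Confidence scores and validation

A cell's confidence in its candidate label is −log10 of the one-sided
rank-sum p-value that the label's marker genes outrank the cell's other
genes (exact for ≤ 10 markers among ≤ 30 tie-free genes, tie-corrected
normal approximation otherwise; a fully tied cell scores −log10 0.5).
Base 10 makes the default threshold 5 read as p < 10⁻⁵; the base and
threshold are config keys.

Scores pooled per candidate label are decomposed by 1-D Gaussian
mixtures: EM with 5 restarts (seeded), equal- and unequal-variance
families, 1–5 components, BIC selection, hard assignment by maximum
posterior. Component count is additionally capped at ⌊n/3⌋ — with
fewer than ~3 points per component BIC happily fits near-singleton
components of vanishing variance. Groups of fewer than 3 cells skip EM
(closed-form single component) and validate only if their mean reaches
the threshold.

Round 1 validates the component with the greatest mean; unvalidated
cells below the threshold become negative controls (validated and
negative-control are mutually exclusive by construction). Round 2
unassigns every component whose mean is *strictly* below the threshold
(a component mean exactly at the threshold keeps its label). When an
atlas is used as the reference, local-reference labels need ≥ 10
validated cells; labels below that are dropped and their cells
reverted.

## Clustering, recapture and the speed-up

Clustering is CP10K log-normalization, scaling (clipped at 10), PCA to
min(50, cells − 1) components, a 20-neighbor SNN graph and Leiden
modularity optimization at resolution 3, all seeded. Recapture relabels
a cluster's `'unassigned'` cells when one label covers strictly more
than 50% of *all* cluster cells (the conservative reading — unassigned
cells count in the denominator) and unassigned cells are strictly fewer
than 20%. Recapture is idempotent and never alters an assigned cell.

Queries above 5000 cells are clustered once; each cluster is split by
seeded k-means (10 restarts) into k = max(1, round(size/m)) sub-clusters
with m = total/3000, and each sub-cluster is summed into one pseudo-cell
— summation keeps counts integral for the round-2 multinomial. The
merged matrix (≈ 3000 pseudo-cells) flows through the full workflow and
labels transfer verbatim to member cells. The same clustering routine
and parameters serve recapture and the speed-up.

## Evaluation metrics

`'unassigned'` is a first-class label: the true type of query cells not
covered by the reference is `'unassigned'`, and balanced accuracy
averages per-true-type accuracies with it included. Labeled variants
remove cells *predicted* `'unassigned'` (configurable to drop truly
unclassifiable cells instead). Cluster accuracy labels each cluster by
plurality vote of predictions and of true types (lexicographic
tie-breaks) and scores their agreement. For the CDI, batch severity is
measured on the top-50 PCs of the merged log-normalized
reference + query matrix: mean silhouette widths under batch and
cell-type labels, each mapped to [0,1] via (ASW+1)/2, combined as
F1_ASW = 2(1−ASW_batch)(ASW_ct)/(1−ASW_batch+ASW_ct); singleton-label
points contribute silhouette 0.

## The synthetic-data generator

Counts are negative binomial (gamma-Poisson) with dispersion 0.3;
per-gene base means are log-normal (σ = 1) and per-cell library sizes
log-normal (σ = 0.25). Dropout emerges from low means rather than an
explicit zero-inflation term. Each cell type owns a disjoint block of
marker genes (default 20 per type) whose means are multiplied by the
fold change (default 8); marker base means are drawn from the upper
half of the expression distribution, since curated markers are
detectably expressed genes. A block of 150 *broad-program* genes is
expressed by every type — reference, unclassifiable and atlas-only —
at its own log-normal activity level (log-mean 2, log-sd 0.75). These
genes are the reason the atlas contrast exists: they survive
one-vs-rest filtering (activity differs between reference types) but
are revealed as non-specific by their breadth across atlas types, and
unclassifiable cells express them too.

The batch model applies one log-normal capture factor per gene
(σ configurable) shared by all query cells, plus a global library-size
rescale; this spans the cross-platform and low-depth axes without
modeling platform chemistry. The atlas has 100 cell types by default —
real organism-wide atlases hold hundreds, and the strict atlas contrast
needs its many-column operating regime; reference-matched columns are
multinomial samples of the reference type means at depth 5·10⁴, and
atlas-only types keep the shared per-gene base structure (expression
magnitude is largely conserved across cell types in aggregated atlases)
with their own disjoint marker blocks and mild per-type noise.

Bundled presets: `situation1_easy` (5 matched types, no batch effect),
`situation2_unclassifiable` (5 shared types × 250 cells + 250 cells of
a novel type, capture σ = 0.5), `situation2_lowdepth` (the severe-batch
pairing: same composition, 0.2× query depth and capture σ = 1.0) and
`atlas_reference` (the atlas itself as the reference). Problem sizes —
2000 genes, 500 reference cells, 1500 query cells — were chosen so a
full two-round run takes tens of seconds on one CPU while every stage
still operates in its intended statistical regime.

**What the simulations do not show.** The generator's batch model is a
monotone per-gene distortion; real cross-platform effects are nonlinear
and gene-family structured, and real low-depth references lose genes
entirely. Marker blocks are perfectly disjoint and cell types are
discrete — there are no continuous differentiation trajectories,
doublets or ambient RNA. Passing the simulated benchmarks therefore
demonstrates the internal correctness and the directional behavior of
the workflow (second round helps under batch stress; the atlas contrast
sharpens rejection of novel types), not its accuracy on any particular
real dataset.

## Numerical conventions

Ranked selections break ties lexicographically by gene symbol or type
name. The top-20% highly expressed filter counts only genes with
nonzero column expression and takes ⌈fraction × expressed⌉ genes.
Gene symbols match case-sensitively after whitespace stripping;
cross-species runs require an explicit ortholog table (unmapped genes
are dropped, many-to-one targets summed). Duplicate gene rows collapse
by summation at load. All randomness — EM restarts, PCA, neighbor
graphs, Leiden, k-means, the generator — is funneled through explicit
seeds; `AnnotateConfig.reseed(seed)` derives every stage seed from one
root value, and identical inputs plus config yield identical results.
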