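# Methods

`isrpipe` re-implements, as a tested and reusable pipeline, the
transcriptomic inference machinery used to localize a chronic integrated
stress response (ISR) to specific CNS cell types: droplet barcode
filtering, iterative SNN/Louvain clustering, marker-based cell-type
probability assignment, cluster-level preranked gene-set enrichment, and
bulk SVD eigengene gene-class extraction. This note documents the models,
the parameters that matter, the synthetic-data generator that the tests
exercise the pipeline on, and the numerical and design choices that were
genuinely open.

## Droplet barcode filtering

Per-barcode total UMI counts in a droplet experiment are bimodal on the
log10 scale: a low mode of empty droplets carrying ambient RNA and a high
mode of cell-containing droplets. The filter histograms log10(UMI totals)
on a uniform grid (`bin_width`, default 0.05 log10 units), smooths with a
centered moving average, and thresholds at the center of the first bin
that is a strict local minimum (plateaus resolve to their left-most bin)
with center at or above a floor (default 2.0, i.e. 100 UMIs). Barcodes at
or above the threshold are retained (deterministic boundary convention).

The smoothing window default is 7 bins. A window of 3 admits single-bin
noise minima on the empty-mode flank, producing spurious thresholds just
above the floor; at 7 the threshold localizes the true inter-mode density
valley to within ±2 bin widths on both well-separated and overlapping mode
configurations. When the modes are very well separated the region between
them receives essentially zero counts over several bins; any
first-minimum rule then lands at the left edge of the empty gap rather
than at the (unidentifiable) density valley. This is immaterial for
filtering — any threshold in the gap classifies barcodes identically — so
the localization property is tested on an overlapping-modes
configuration, and the default configuration is tested on retention
(≥ 99% of cells kept, ≤ 1% of empties).

## Normalization, variable genes, PCA

Counts are depth-scaled to 10^4 per barcode and log1p-transformed.
Variable genes are selected Seurat-v2-style: per-gene mean and dispersion
(variance/mean) computed on the de-logged scale, genes binned into 20
equal-occupancy bins by log mean, dispersion z-scored within bin; genes
with z ≥ 1 and log-mean in [0.0125, 8] are kept. The upper mean bound of 8
(the Seurat `x.high.cutoff` default) matters during sub-clustering: within
a two-type subset a marker's mean expression is several-fold its full-data
mean, and a tighter bound (e.g. 3) silently discards exactly the genes
that would justify a split.

Cells are embedded by PCA on the centered, per-gene unit-scaled variable
genes, retaining 50 components. Below 5000 cells the deterministic full
SVD solver is used; above, seeded randomized SVD. Zero-variance genes are
dropped with a warning. Sign is fixed by the SVD solver's deterministic
convention; tests treat per-component sign as arbitrary.

## SNN graph and iterative Louvain clustering

Each cell's neighbor set is itself plus its K = min(750, n_cells − 1)
nearest neighbors by Euclidean distance in PC space (distance ties break
toward the lower cell index). Edges are weighted by the Jaccard index of
neighbor sets and pruned below 1/15 — the cutoff is interpreted as a
*similarity* floor, the standard SNN pruning convention; reading it as a
distance cutoff would discard exactly the strong edges.

Louvain community detection (igraph's multilevel implementation) maximizes
resolution-scaled modularity
Q(r) = Σ_c [ W_in(c)/W_tot − r·(S_c/(2·W_tot))² ].
The greedy sweep follows vertex and edge order, so the seed permutes
vertex ids and shuffles the edge list before each run; on all tested
graphs of ≤ 8 nodes the best of 10 seeds attains the
exhaustive-enumeration optimum of Q(r).

The resolution is chosen by scanning 0.05–1.225 in steps of 0.025
(48 points) and maximizing a partition quality metric, the mean over
communities of (unifiability + isolability)/2 where

- unifiability(c) = W_in(c) / (|c|·(|c|−1)/2), the weighted internal edge
  density (1 for singletons), penalizing over-merging;
- isolability(c) = 1 − W_cut(c)/(W_in(c)+W_cut(c)), the complement of the
  cut fraction (1 for communities with no incident edges), penalizing
  over-splitting.

Both terms are bounded by 1 (weights are Jaccard indices ≤ 1), so the
metric lies in [0, 1]; it equals 1 exactly for a partition into disjoint
cliques. Ties in the scan resolve toward the smallest resolution. The
metric is deliberately isolated behind one function so it can be swapped.

Clustering is then repeated on each cluster alone — variable genes
re-selected, cells re-embedded, SNN rebuilt, resolution re-scanned. A leaf
splits when the selected sub-partition has ≥ 2 communities of ≥ 10 cells
each *and* the mean metric contribution of the children, evaluated on the
root SNN graph, is at least the leaf's own contribution; the second
condition stops homogeneous clusters from fragmenting along density
fluctuations. Convergence is reached when no leaf splits. Labels are
hierarchical dot-paths (`"3.1"`); leaves are processed in ascending label
order, so reruns are identical.

## Bimodal likelihood-ratio differential expression

A gene's normalized expression in a group is modeled as a point mass at
zero with probability 1 − π mixed with a Gaussian(μ, σ) over positive
values. Maximum likelihood is closed-form (π = detection fraction; μ, σ
from the positive values, σ floored at 10⁻³). The test statistic is
2(ℓ_A + ℓ_B − ℓ_pooled), referred to χ²(3); when either group has fewer
than two positive observations the Gaussian part is dropped for both
groups and the test reduces to a χ²(1) LRT on the detection probability.
Under its own null the empirical type-I error at α = 0.05 is ≈ 0.05–0.065
(n = 50 per group): the χ² reference is mildly anti-conservative at this
sample size, within the tolerance the tests assert ([0.03, 0.07]).

Markers of a cluster are genes tested against all other cells (detection
prefilter: ≥ 10% in either group), Bonferroni-adjusted, flagged at
adjusted p < 0.05 with the higher mean in the cluster. Bonferroni is the
default because it matches the toolchain era; Benjamini–Hochberg is
available (`adjust_method="bh"`). Ranked lists for enrichment use
direction × (−log10 p), ties broken by LRT statistic then gene id, so the
ordering is total and deterministic.

## Cell-type probability assignment

For each cluster and candidate cell type: every marker of the type
detected in the cluster (count > 0 in ≥ 1 cell; a minimum detection
fraction is configurable) contributes its mean normalized expression over
*all* cluster cells times its detection fraction; the sum is divided by
the type's total marker count — detected or not — so types with larger
reference panels are not favored. Raw scores are normalized to sum to one
across types and read as probabilities; the cluster is assigned the argmax
type only when its probability strictly exceeds 0.5, otherwise it is
`UNASSIGNED`. Scores are scale-equivariant, so probabilities and
assignments are invariant to rescaling the expression matrix.

## Preranked GSEA

The enrichment score is the signed maximal deviation of the weighted
Kolmogorov–Smirnov running sum (hit increments |stat|^p normalized over
the set, p = 1 by default; miss decrements 1/(N − |set|)). The
implementation evaluates the running sum only at positions adjacent to
hits, which is exact because the sum is linear between hits; tests verify
equality with a definitional gene-by-gene recomputation to floating-point
round-off. If every set member has statistic 0, hits fall back to equal
weights.

The null is gene-permutation: random same-size sets drawn without
replacement from the ranked universe. Nominal p is the one-sided tail
frequency on the matching sign with a +1 pseudo-count; NES divides ES by
the mean |null ES| of the same sign; q-values are Benjamini–Hochberg
across the batch. Within one call, null distributions are cached per set
size — sets of equal size share one null sample. This is a fair p-value
for each set but correlates p-values *across* sets in the batch;
calibration experiments that need independent replicates should call
`gsea_preranked` once per set with distinct seeds (as the packaged
calibration does).

`cluster_signature_analysis` builds the two contrast families of the
cell-type-resolved ISR analysis: per cluster, WT cells versus all other WT
cells (basal family), and mutant versus WT cells within the cluster
(genotype family; clusters missing a genotype are skipped with a
warning). q-values are adjusted within each family across all
(cluster, set) results — the multiple-testing family behind per-cluster
q-values is not otherwise determined, and per-family adjustment is the
most conservative of the plausible readings. A cluster "shows" the
signature when q < 0.05 with positive ES; negatively enriched clusters
(signature relatively depleted) also reach small q and are reported with
their sign.

## Bulk SVD eigengenes

A genes × samples TPM matrix is ln(x+1)-transformed and per-gene centered
(both flags exposed; without centering the first component captures mean
expression rather than the genotype contrast), then factored by exact
SVD. Right singular vectors are the eigengenes (canonical patterns across
samples); variance fractions are s_k²/Σs². Each component is sign-fixed so
its largest-magnitude sample entry is nonnegative; which biological group
ends up positive is still conventional, so consumers orient classes by
the group projection. Gene classes on a component: threshold = 2 × mean
absolute loading; up class = loadings above +threshold, down class below
−threshold.

## The synthetic-data generator

The droplet generator emulates the structure of the study's data, not its
content: two concatenated samples (one per genotype) with an expected
recovery of 4000 cells each — clustering in the study ran on concatenated
samples, and type sizes larger than K are the regime in which
K = min(750, n−1) SNN graphs have within-type neighbor sets — giving 10
transcriptionally distinct cell types of 800 cells (400 per genotype) over
2000 genes, plus 8000 empty droplets.

Per cell type, 50 marker genes are enriched `marker_fold` (default 4)
over baseline in their type and suppressed by `marker_fold⁻²` elsewhere
(64-fold on/off ratio at the default — conservative relative to real
sorted-bulk marker panels, whose on/off ratios often exceed 100, and
constructed so that `marker_fold = 1` is an exact null). Marker baselines
are drawn from lognormal(0.5, 0.8) rather than the genome-wide
lognormal(0, 1), reflecting that curated references contain robustly
expressed genes. A 95-gene ISR signature (disjoint from markers) is
elevated 2-fold basally in the two astrocyte-like types and a further
1.5-fold in those types in the mutant genotype. Per-barcode totals are
10^Normal: cells (3.5, 0.2), empties (1.5, 0.3); gene counts are
multinomial given the total, which preserves the UMI-total structure the
barcode filter exploits (independent Poisson would not). Empty droplets
sample the cell-abundance-weighted average program. Ground truth (barcode
→ type/genotype, marker map, signature, bulk classes) is returned for
recovery testing.

The bulk generator plants 473 up- and 600 down-regulated genes (fold 4)
in the mutant group of a 3 vs 3 contrast over 12000 genes, with
multiplicative lognormal replicate noise (sd 0.15, ~15% CV, typical for
inbred-mouse bulk replicates) and TPM column normalization. The TPM
constraint couples genes: the asymmetric planted mass shifts all null
genes' loadings slightly in one direction — a real compositional effect
that the two-fold-mean threshold must tolerate, and does at realistic
noise.

What the generator does *not* model: doublets, batch effects, ambient
contamination inside cells, mitochondrial content, gene–gene correlation
beyond the type programs, UMI saturation, and library-size/type
confounding. Passing recovery tests therefore demonstrates that the
implementation recovers planted structure under the stated statistical
model, not that the pipeline is robust to every artifact of real droplet
data.

## Problem sizes used in tests

The packaged test-suite and acceptance script run the full default
simulation (16000 barcodes) once and replicate the multi-seed checks
(assignment accuracy, signature detection) on a structure-preserving
scaled configuration — the same 10-type design at 160 cells/type with
1600 empties and K cap 150, keeping K below the type size as in the full
configuration. Bulk analyses run at full default size (they are cheap).
Self-calibrations use 2000 replicates (LRT) and 2000 independent
replicate sets at 500 permutations each (GSEA).

## Known limitations

- The partition-quality metric is a reasoned reconstruction; other
  bounded density/cut trade-offs would select different resolutions on
  ambiguous graphs.
- The χ²(3) reference of the bimodal LRT is asymptotic; at tens of cells
  per group the test is mildly anti-conservative (~6% at α = 5%).
- Gene-permutation GSEA ignores inter-gene correlation; sample
  permutation is impossible from a preranked list.
- With K greater than the true population sizes, SNN/Jaccard graphs
  cannot isolate those populations (neighbor sets necessarily span
  types); this is a property of the method, and the generator's defaults
  are chosen to reflect the data regime the method was designed for.
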