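# isrpipe

Cell-type-resolved analysis of chronic integrated-stress-response (ISR)
activation in brain transcriptomes. The package is for computational
biologists who need the full inference chain behind studies of eIF2B
hypomorphic (VWM-model) mice: which CNS cell types express an ISR gene
signature basally, and in which cell types a mutant genotype elevates it
further — plus the bulk-RNA-seq eigengene analysis that extracts the
genotype-driven gene classes.

## What it computes

**Droplet scRNA-seq pipeline** (10x-style MTX/TSV triples in, TSV/JSON
out):

1. *Barcode filtering* — cell-containing barcodes are separated from empty
   droplets at the first local minimum above 2 in the distribution of
   log10(UMI totals).
2. *Embedding* — depth normalization (10⁴, log1p), dispersion-based
   variable-gene selection, PCA retaining 50 components.
3. *Clustering* — shared-nearest-neighbor graph with
   K = min(750, #cells − 1) and Jaccard edge weights pruned below 1/15;
   Louvain community detection over a resolution grid (0.05–1.225),
   selecting the resolution that maximizes the mean
   unifiability/isolability partition metric; each cluster is then
   re-analyzed alone, iteratively, until no cluster can be broken into
   sub-clusters.
4. *Differential expression* — a bimodal likelihood-ratio test (point mass
   at zero + Gaussian over positive values per group; LRT against a pooled
   model, χ²(3), with a 1-df detection-only fallback). Cluster markers are
   genes overexpressed versus all other cells at Bonferroni-adjusted
   p < 0.05.
5. *Cell-type assignment* — for each cluster and candidate type, every
   detected marker contributes (mean expression over all cluster cells) ×
   (detection fraction); the sum is divided by the type's total marker
   count, scores are normalized to probabilities, and the cluster is
   assigned the top type when its probability exceeds 0.5.
6. *Signature enrichment* — preranked GSEA (weighted Kolmogorov–Smirnov
   enrichment score, gene-permutation null, BH q-values) on two contrast
   families: each cluster's WT cells versus all other WT cells (basal ISR),
   and mutant versus WT cells within each cluster (genotype ISR).

**Bulk pipeline**: SVD of a genes × samples ln(TPM+1) matrix (per-gene
centered). The right singular vectors — *eigengenes* — are canonical
expression patterns across samples; gene classes on a component are genes
whose |loading| exceeds two-fold the mean absolute loading, split by sign.

**Synthetic data**: `simulate_droplets` / `simulate_bulk` generate
datasets with the statistical structure these analyses assume (distinct
marker-defined cell types, an astrocyte-like class with elevated basal
signature expression, genotype-responsive types, empty droplets, planted
bulk gene classes) together with full ground truth, so every stage is
testable by parameter recovery.

## Worked example

```python
import isrpipe as ip
from sklearn.metrics import adjusted_rand_score

sim = ip.CellSimConfig(seed=7, cells_per_type=160, n_empty_droplets=1600)
counts, truth, reference, gene_sets = ip.simulate_droplets(sim)

cfg = ip.PipelineConfig(seed=0, k_cap=150)
res = ip.run_pipeline(
    cfg, counts=counts, marker_reference=reference, gene_sets=gene_sets,
    genotype_of_barcode=dict(
        zip(truth.barcodes.index, truth.barcodes["genotype"])
    ),
    out_dir="results/demo",
)

print(f"threshold: {res['threshold']:.3f} log10(UMI)")
print(f"barcodes retained: {res['filtered'].n_barcodes} / {counts.n_barcodes}")
asg = res["assignment"]
types = truth.barcodes.loc[asg.barcode_ids, "cell_type"].to_numpy()
print(f"clusters: {asg.n_clusters}, ARI vs planted types: "
      f"{adjusted_rand_score(types, asg.final):.3f}")
enr = res["enrichment"]
flagged = enr[(enr.q_value < 0.05) & (enr.es > 0)]
print(flagged[["family", "cluster", "es", "nes", "q_value"]].round(3))
```

Output:

```
threshold: 2.675 log10(UMI)
barcodes retained: 1600 / 3200
clusters: 10, ARI vs planted types: 1.000
  family cluster    es   nes  q_value
   basal       1 0.956 1.545    0.006
   basal       7 0.960 1.538    0.006
genotype       1 0.937 2.613    0.006
genotype       7 0.939 2.581    0.006
```

The filter keeps exactly the 1600 true cells (threshold 2.675 sits in the
gap between the empty and cell UMI modes); clustering recovers the ten
planted types perfectly; and the enrichment step flags clusters 1 and 7 —
which `res["cell_types"]` identifies as `bergmann_glia` and `astrocytes`,
the two types simulated with elevated basal signature expression — as
significantly enriched (q ≈ 0.006) in both the basal and the
genotype-contrast family, while all other clusters stay below the
significance line. This mirrors the biological finding the pipeline is
built around: astrocyte-lineage cells carry the ISR signature basally and
upregulate it further in the mutant.

The same stages are exposed as sklearn-style estimators
(`BarcodeFilter`, `LogNormalizer`, `VariableGeneSelector`, `PCAEmbedder`,
`SnnLouvainClusterer`, `CellTypeScorer`, `EigengeneSVD`) with
`fit`/`transform`/`get_params`, and as a CLI:

```bash
isrpipe --seed 1 --out results simulate
isrpipe --out results qc results/counts
isrpipe --out results eigengene results/bulk_tpm.tsv
isrpipe --seed 1 --out results run-all results/counts \
    --markers-tsv results/marker_reference.tsv \
    --gmt results/signature.gmt --genotypes results/truth_barcodes.tsv
```

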