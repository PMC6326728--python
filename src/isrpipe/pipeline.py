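"""End-to-end pipeline: qc -> embed -> cluster -> markers -> celltype -> gsea.

Each stage writes a diff-able TSV/JSON artifact into the output directory
and logs the parameter values actually used; a run is a pure function of
(inputs, config, seed), so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .celltype import assign_all
from .cluster import (
    Partition,
    SubclusterConfig,
    build_knn,
    build_snn_jaccard,
    iterative_subcluster,
    resolution_search,
)
from .config import PipelineConfig
from .containers import CountMatrix, GeneSetCollection, MarkerReference
from .de import all_markers
from .embed import compute_pca, normalize_counts, select_variable_genes
from .gsea import cluster_signature_analysis
from .qc import build_umi_histogram, filter_barcodes, find_umi_threshold

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: PipelineConfig,
    counts: CountMatrix | None = None,
    counts_dir: str | Path | None = None,
    marker_reference: MarkerReference | str | Path | None = None,
    gene_sets: GeneSetCollection | str | Path | None = None,
    genotype_of_barcode: dict[str, str] | str | Path | None = None,
    out_dir: str | Path = "results",
    stages: tuple[str, ...] = (
        "qc", "embed", "cluster", "markers", "celltype", "gsea",
    ),
) -> dict:
    """Run the single-cell stages in order, writing per-stage outputs.

    ``genotype_of_barcode`` (mapping or two-column TSV barcode/genotype) is
    required for the gsea stage; ``marker_reference`` for celltype;
    ``gene_sets`` (GMT) for gsea. Inputs are validated before any stage
    runs. Returns a dict of in-memory stage results.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # resolve inputs up front so missing requirements fail before stage 1
    if counts is None:
        if counts_dir is None:
            raise ValueError("either counts or counts_dir is required")
        d = Path(counts_dir)
        counts = io.read_counts_10x(
            d / "matrix.mtx", d / "barcodes.tsv", d / "features.tsv"
        )
    if "celltype" in stages:
        if marker_reference is None:
            raise ValueError("celltype stage requested without marker_reference")
        if not isinstance(marker_reference, MarkerReference):
            marker_reference = io.read_marker_reference(marker_reference)
    if "gsea" in stages:
        if gene_sets is None:
            raise ValueError("gsea stage requested without gene_sets")
        if not isinstance(gene_sets, GeneSetCollection):
            gene_sets = io.read_gene_sets_gmt(gene_sets)
        if genotype_of_barcode is None:
            raise ValueError("gsea stage requested without genotype labels")
        if not isinstance(genotype_of_barcode, dict):
            df = pd.read_csv(genotype_of_barcode, sep="\t")
            genotype_of_barcode = dict(
                zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))
            )

    (out / "parameters.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    logger.info("effective parameters: %s", config.to_dict())

    results: dict = {"config": config}
    grid = config.resolution_grid()

    def stage(name):
        logger.info("running stage %s", name)

    try:
        stage("qc")
        hist = build_umi_histogram(
            counts, bin_width=config.bin_width,
            smooth_window=config.smooth_window, floor=config.umi_floor,
        )
        threshold = find_umi_threshold(hist)
        filtered = filter_barcodes(counts, threshold)
        (out / "qc_threshold.json").write_text(json.dumps({
            "log10_umi_threshold": threshold,
            "n_barcodes_in": counts.n_barcodes,
            "n_barcodes_retained": filtered.n_barcodes,
        }, indent=2) + "\n")
        io.write_counts_10x(filtered, out / "filtered_counts")
        results["threshold"] = threshold
        results["filtered"] = filtered
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("qc", exc) from exc
    if "embed" not in stages:
        return results

    try:
        stage("embed")
        normalized = normalize_counts(filtered, scale_factor=config.scale_factor)
        var_genes = select_variable_genes(
            normalized, n_bins=config.n_bins, z_cutoff=config.z_cutoff,
            mean_bounds=config.mean_bounds,
        )
        embedding = compute_pca(
            normalized, var_genes, n_pcs=config.n_pcs,
            random_state=config.seed,
        )
        pd.Series(var_genes, name="gene").to_csv(
            out / "variable_genes.tsv", sep="\t", index=False
        )
        emb_df = pd.DataFrame(
            embedding.coordinates,
            index=pd.Index(embedding.barcode_ids, name="barcode"),
            columns=[f"PC{i+1}" for i in range(embedding.n_pcs)],
        )
        io.write_table(emb_df, out / "embedding.tsv", index=True)
        results["normalized"] = normalized
        results["embedding"] = embedding
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("embed", exc) from exc
    if "cluster" not in stages:
        return results

    try:
        stage("cluster")
        neighbors = build_knn(embedding, k_cap=config.k_cap)
        graph = build_snn_jaccard(
            neighbors, prune_cutoff=config.prune_cutoff,
            node_ids=embedding.barcode_ids,
        )
        scan = resolution_search(graph, grid=grid, seed=config.seed)
        sub_cfg = SubclusterConfig(
            k_cap=config.k_cap, prune_cutoff=config.prune_cutoff,
            resolution_grid=grid, min_cells=config.min_cells,
            n_pcs=config.n_pcs, n_bins=config.n_bins,
            z_cutoff=config.z_cutoff, mean_bounds=config.mean_bounds,
        )
        assignment = iterative_subcluster(
            normalized, scan.selected_partition, config=sub_cfg,
            seed=config.seed, root_graph=graph,
        )
        cl_df = pd.DataFrame({
            "barcode": assignment.barcode_ids,
            "hierarchical_label": assignment.hierarchical,
            "final_label": assignment.final,
        })
        io.write_table(cl_df, out / "clusters.tsv")
        (out / "resolution_scan.json").write_text(json.dumps({
            "resolutions": [float(r) for r in scan.resolutions],
            "metric": [float(m) for m in scan.metrics],
            "selected_resolution": scan.selected_resolution,
            "n_top_level_clusters": scan.selected_partition.n_communities,
            "n_final_clusters": assignment.n_clusters,
        }, indent=2) + "\n")
        results["graph"] = graph
        results["scan"] = scan
        results["assignment"] = assignment
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cluster", exc) from exc
    if "markers" not in stages:
        return results

    try:
        stage("markers")
        markers = all_markers(
            normalized, assignment, min_frac=config.min_detect_frac,
            alpha=config.marker_alpha, method=config.adjust_method,
        )
        io.write_table(markers[markers["is_marker"]], out / "markers.tsv")
        results["markers"] = markers
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("markers", exc) from exc
    if "celltype" not in stages:
        return results

    try:
        stage("celltype")
        celltype_table = assign_all(
            normalized, assignment, marker_reference,
            threshold=config.prob_threshold,
        )
        io.write_table(celltype_table, out / "cell_types.tsv")
        results["cell_types"] = celltype_table
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("celltype", exc) from exc
    if "gsea" not in stages:
        return results

    try:
        stage("gsea")
        genotypes = np.array([
            genotype_of_barcode.get(b, "") for b in normalized.barcode_ids
        ])
        wt, mut = config.genotype_labels
        enrichment = cluster_signature_analysis(
            normalized, assignment, genotypes, gene_sets,
            wt_label=wt, mut_label=mut, n_perm=config.n_perm,
            seed=config.seed, weight_exponent=config.weight_exponent,
        )
        io.write_table(enrichment, out / "enrichment.tsv")
        results["enrichment"] = enrichment
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("gsea", exc) from exc
    return results
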