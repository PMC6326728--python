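"""Shared fixtures: simulations and pipeline runs reused across test modules.

The full-size default simulation and its pipeline run are expensive, so they
are session-scoped and shared by the unit tests and the acceptance tests.
Multi-seed checks use a structure-preserving scaled configuration (same 10
types and signature design, 160 cells/type, proportionate K cap).
"""

from __future__ import annotations

import numpy as np
import pytest

import isrpipe as ip

SCALED_KWARGS = dict(cells_per_type=160, n_empty_droplets=1600)
SCALED_K_CAP = 150


@pytest.fixture(scope="session")
def default_sim():
    """Full default droplet simulation (10 types x 800 cells + 8000 empties)."""
    cfg = ip.CellSimConfig(seed=1)
    counts, truth, reference, gene_sets = ip.simulate_droplets(cfg)
    return {
        "config": cfg,
        "counts": counts,
        "truth": truth,
        "reference": reference,
        "gene_sets": gene_sets,
    }


@pytest.fixture(scope="session")
def default_run(default_sim, tmp_path_factory):
    """Full pipeline run on the default simulation (shared, ~2.5 min)."""
    truth = default_sim["truth"]
    cfg = ip.PipelineConfig(seed=0)
    results = ip.run_pipeline(
        cfg,
        counts=default_sim["counts"],
        marker_reference=default_sim["reference"],
        gene_sets=default_sim["gene_sets"],
        genotype_of_barcode=dict(
            zip(truth.barcodes.index, truth.barcodes["genotype"])
        ),
        out_dir=tmp_path_factory.mktemp("default_run"),
    )
    results["truth"] = truth
    return results


def run_scaled(seed: int, tmp_path, sim_kwargs=None, **pipeline_kwargs):
    """One scaled simulation + pipeline run; returns (results, truth)."""
    kwargs = dict(SCALED_KWARGS)
    if sim_kwargs:
        kwargs.update(sim_kwargs)
    cfg = ip.CellSimConfig(seed=seed, **kwargs)
    counts, truth, reference, gene_sets = ip.simulate_droplets(cfg)
    pcfg = ip.PipelineConfig(seed=0, k_cap=SCALED_K_CAP, **pipeline_kwargs)
    results = ip.run_pipeline(
        pcfg,
        counts=counts,
        marker_reference=reference,
        gene_sets=gene_sets,
        genotype_of_barcode=dict(
            zip(truth.barcodes.index, truth.barcodes["genotype"])
        ),
        out_dir=tmp_path,
    )
    return results, truth


@pytest.fixture(scope="session")
def scaled_runs(tmp_path_factory):
    """Twenty scaled pipeline runs over distinct simulation seeds."""
    runs = []
    for seed in range(20):
        out = tmp_path_factory.mktemp(f"scaled_{seed}")
        runs.append(run_scaled(seed, out))
    return runs


def majority_type(truth, assignment, cluster: int) -> str:
    """Dominant planted cell type among a cluster's cells."""
    barcodes = np.array(assignment.barcode_ids)[assignment.cells_of(cluster)]
    types = truth.barcodes.loc[barcodes, "cell_type"]
    return types.mode().iloc[0]
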