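"""Preranked gene-set enrichment with a gene-permutation null.

The enrichment score (ES) is the signed maximal deviation of the weighted
Kolmogorov-Smirnov running sum over a ranked gene list: genes in the set
increment the sum by |stat|^p / sum_set |stat|^p (weight exponent p,
default 1) and genes outside it decrement by 1/(N - set size). The null
distribution per set is built from random same-size gene sets drawn without
replacement from the ranked universe; the nominal p is the one-sided tail
frequency on the matching sign with a +1 pseudo-count, NES is the ES
divided by the mean |null ES| of the same sign, and q-values are
Benjamini-Hochberg across all results of a batch.

``cluster_signature_analysis`` reproduces the two contrast families of the
cell-type-resolved ISR analysis: per-cluster basal enrichment (WT cells of
the cluster vs all other WT cells) and per-cluster genotype enrichment
(mutant vs WT cells within the cluster).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import GeneSetCollection, NormalizedMatrix
from .cluster import ClusterAssignment
from .de import ranked_list, _adjust

logger = logging.getLogger(__name__)

__all__ = [
    "enrichment_score",
    "gsea_preranked",
    "cluster_signature_analysis",
]


def _hit_positions(ranked_genes: np.ndarray, gene_set) -> np.ndarray:
    members = set(gene_set)
    return np.flatnonzero(np.fromiter(
        (g in members for g in ranked_genes), bool, len(ranked_genes)
    ))


def _es_from_positions(
    weights: np.ndarray, positions: np.ndarray, n_genes: int
) -> float:
    """ES from sorted hit positions; ``weights`` = |stat|^p at those hits.

    The running sum is piecewise linear between hits, so its extrema occur
    immediately after a hit (local max candidates) or immediately before
    one (local min candidates); the signed maximal deviation is returned.
    """
    k = positions.size
    miss_step = 1.0 / (n_genes - k)
    wsum = weights.sum()
    if wsum > 0:
        hit_steps = weights / wsum
    else:  # all-zero stats inside the set: fall back to equal hit weights
        hit_steps = np.full(k, 1.0 / k)
    cum_hits = np.cumsum(hit_steps)
    misses_before = positions - np.arange(k)
    after = cum_hits - misses_before * miss_step
    before = np.concatenate(([0.0], cum_hits[:-1])) - misses_before * miss_step
    hi = after.max()
    lo = before.min()
    return float(hi if hi >= -lo else lo)


def enrichment_score(
    ranked: pd.DataFrame | tuple,
    gene_set,
    weight_exponent: float = 1.0,
) -> float:
    """Weighted KS enrichment score of ``gene_set`` in a ranked list.

    ``ranked`` is either a frame with columns ``gene`` and ``stat`` (sorted
    descending, as produced by :func:`isrpipe.de.ranked_list`) or a tuple
    ``(genes, stats)`` in ranked order.
    """
    if isinstance(ranked, pd.DataFrame):
        genes = ranked["gene"].to_numpy()
        stats = ranked["stat"].to_numpy(dtype=float)
    else:
        genes, stats = ranked
        genes = np.asarray(genes)
        stats = np.asarray(stats, dtype=float)
    positions = _hit_positions(genes, gene_set)
    if positions.size == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if positions.size == genes.size:
        raise ValueError("gene set covers the entire ranked list")
    weights = np.abs(stats[positions]) ** weight_exponent
    return _es_from_positions(weights, positions, genes.size)


def _null_es(
    abs_stats_w: np.ndarray, set_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES of ``n_perm`` random same-size sets (vectorized)."""
    n = abs_stats_w.size
    out = np.empty(n_perm)
    miss_step = 1.0 / (n - set_size)
    ar = np.arange(set_size)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n, size=set_size, replace=False))
        w = abs_stats_w[pos]
        wsum = w.sum()
        hit = w / wsum if wsum > 0 else np.full(set_size, 1.0 / set_size)
        cum = np.cumsum(hit)
        after = cum - (pos - ar) * miss_step
        before = np.concatenate(([0.0], cum[:-1])) - (pos - ar) * miss_step
        hi = after.max()
        lo = before.min()
        out[i] = hi if hi >= -lo else lo
    return out


def gsea_preranked(
    ranked: pd.DataFrame,
    gene_sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    adjust_batch: bool = True,
) -> pd.DataFrame:
    """Preranked GSEA of every set in ``gene_sets`` against one ranked list.

    Null distributions are cached per set size, so collections of same-size
    sets cost a single permutation pass. With ``adjust_batch`` the q column
    is BH-adjusted across the rows of this call; callers assembling larger
    families should adjust across the combined table instead.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = ranked["gene"].to_numpy()
    stats = ranked["stat"].to_numpy(dtype=float)
    abs_w = np.abs(stats) ** weight_exponent
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, members in gene_sets:
        positions = _hit_positions(genes, members)
        es = enrichment_score((genes, stats), members, weight_exponent)
        k = positions.size
        if k not in null_cache:
            null_cache[k] = _null_es(abs_w, k, n_perm, rng)
        null = null_cache[k]
        same_sign = null >= 0 if es >= 0 else null < 0
        n_sign = int(same_sign.sum())
        extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p = (extreme + 1.0) / (n_sign + 1.0)
        mean_same = np.abs(null[same_sign]).mean() if n_sign else np.nan
        nes = es / mean_same if n_sign and mean_same > 0 else np.nan
        rows.append({
            "gene_set": name,
            "size": k,
            "es": es,
            "nes": nes,
            "p_value": p,
            "n_perm": n_perm,
            "seed": seed,
        })
    out = pd.DataFrame(rows)
    if adjust_batch:
        out["q_value"] = _adjust(out["p_value"].to_numpy(), "bh")
    return out


def cluster_signature_analysis(
    normalized: NormalizedMatrix,
    assignment: ClusterAssignment,
    genotypes: np.ndarray | pd.Series,
    gene_sets: GeneSetCollection,
    wt_label: str = "WT",
    mut_label: str = "MUT",
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Per-cluster signature enrichment in the two contrast families.

    Family ``basal``: for each cluster, WT cells of the cluster vs WT cells
    of all other clusters. Family ``genotype``: mutant vs WT cells within
    each cluster (clusters missing a genotype are skipped with a warning).
    q-values are BH-adjusted within each family across clusters and sets.
    """
    genotypes = np.asarray(genotypes)
    if genotypes.size != normalized.n_barcodes:
        raise ValueError("one genotype label per barcode required")
    present = set(genotypes)
    if wt_label not in present or mut_label not in present:
        raise ValueError("both genotypes must be present")
    is_wt = genotypes == wt_label
    is_mut = genotypes == mut_label
    leaf_names = assignment.leaf_labels

    frames = []
    for family in ("basal", "genotype"):
        fam_rows = []
        for c in range(assignment.n_clusters):
            cells = assignment.cells_of(c)
            in_cluster = np.zeros(normalized.n_barcodes, bool)
            in_cluster[cells] = True
            if family == "basal":
                a = np.flatnonzero(in_cluster & is_wt)
                b = np.flatnonzero(~in_cluster & is_wt)
                desc = f"{leaf_names[c]}:WT_vs_otherWT"
            else:
                a = np.flatnonzero(in_cluster & is_mut)
                b = np.flatnonzero(in_cluster & is_wt)
                desc = f"{leaf_names[c]}:{mut_label}_vs_{wt_label}"
            if a.size == 0 or b.size == 0:
                logger.warning(
                    "cluster %s lacks cells for the %s contrast; skipped",
                    leaf_names[c], family,
                )
                continue
            rl = ranked_list(normalized, a, b, descriptor=desc)
            res = gsea_preranked(
                rl, gene_sets, n_perm=n_perm, seed=seed,
                weight_exponent=weight_exponent, adjust_batch=False,
            )
            res.insert(0, "cluster", leaf_names[c])
            res.insert(0, "contrast", desc)
            res.insert(0, "family", family)
            fam_rows.append(res)
        if fam_rows:
            fam = pd.concat(fam_rows, ignore_index=True)
            fam["q_value"] = _adjust(fam["p_value"].to_numpy(), "bh")
            frames.append(fam)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
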