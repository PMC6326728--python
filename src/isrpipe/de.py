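"""Bimodal likelihood-ratio differential expression and ranked gene lists.

Single-cell log-normalized expression of a gene is modeled per group as a
point mass at zero (probability 1 - pi) mixed with a Gaussian over the
positive observations (probability pi). The likelihood-ratio test compares
separate models for the two groups against a pooled model; with 3 free
parameters per model (pi, mu, sigma) the statistic is referred to a
chi-square with 3 degrees of freedom. When either group has fewer than two
positive observations the Gaussian component is dropped for both groups and
the test reduces to a 1-df LRT on the detection probability alone.

Cluster markers are genes significantly overexpressed in a cluster versus
all other cells (adjusted p < 0.05, positive direction). Ranked lists for
gene-set enrichment order genes by signed -log10 p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .containers import NormalizedMatrix
from .cluster import ClusterAssignment

__all__ = [
    "BimodTestResult",
    "bimod_lrt",
    "markers_for_cluster",
    "all_markers",
    "ranked_list",
]

SIGMA_MIN = 1e-3


@dataclass
class BimodTestResult:
    gene_id: str
    lrt_stat: float
    p_value: float
    adjusted_p: float
    direction: int
    mean_a: float
    mean_b: float
    detect_frac_a: float
    detect_frac_b: float
    df: int = 3


def _group_stats(x: np.ndarray):
    """(n, n_pos, sum_pos, sumsq_pos) of a 1-D value array."""
    pos = x[x > 0]
    return x.size, pos.size, pos.sum(), np.square(pos).sum()


def _binom_ll(n_pos, n):
    """Maximized Bernoulli log-likelihood of the detection indicator."""
    n_zero = n - n_pos
    ll = 0.0
    if n_pos > 0:
        ll += n_pos * np.log(n_pos / n)
    if n_zero > 0:
        ll += n_zero * np.log(n_zero / n)
    return ll


def _gauss_ll(n_pos, s, ss, sigma_min=SIGMA_MIN):
    """Maximized Gaussian log-likelihood of the positive observations."""
    if n_pos == 0:
        return 0.0
    mu = s / n_pos
    var = max(ss / n_pos - mu * mu, sigma_min**2)
    return -0.5 * n_pos * (np.log(2 * np.pi * var) + 1.0) if var > sigma_min**2 \
        else -0.5 * n_pos * (np.log(2 * np.pi * sigma_min**2)
                             + (ss / n_pos - mu * mu) / sigma_min**2)


def bimod_lrt(
    values_a: np.ndarray,
    values_b: np.ndarray,
    gene_id: str = "",
    sigma_min: float = SIGMA_MIN,
) -> BimodTestResult:
    """Bimodal LRT between two groups of normalized log expression values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    na, ka, sa, ssa = _group_stats(a)
    nb, kb, sb, ssb = _group_stats(b)
    stat, p, df = _lrt_from_stats(na, ka, sa, ssa, nb, kb, sb, ssb, sigma_min)
    mean_a, mean_b = a.mean(), b.mean()
    return BimodTestResult(
        gene_id=gene_id,
        lrt_stat=stat,
        p_value=p,
        adjusted_p=p,
        direction=int(np.sign(mean_a - mean_b)),
        mean_a=mean_a,
        mean_b=mean_b,
        detect_frac_a=ka / na,
        detect_frac_b=kb / nb,
        df=df,
    )


def _lrt_from_stats(na, ka, sa, ssa, nb, kb, sb, ssb, sigma_min=SIGMA_MIN):
    full_gauss = ka >= 2 and kb >= 2
    ll_a = _binom_ll(ka, na)
    ll_b = _binom_ll(kb, nb)
    ll_pool = _binom_ll(ka + kb, na + nb)
    if full_gauss:
        ll_a += _gauss_ll(ka, sa, ssa, sigma_min)
        ll_b += _gauss_ll(kb, sb, ssb, sigma_min)
        ll_pool += _gauss_ll(ka + kb, sa + sb, ssa + ssb, sigma_min)
        df = 3
    else:
        df = 1
    stat = max(2.0 * (ll_a + ll_b - ll_pool), 0.0)
    p = float(stats.chi2.sf(stat, df))
    return stat, p, df


def _matrix_group_stats(values: sp.csr_matrix, cells: np.ndarray):
    """Vectorized per-gene stats over a cell subset of a genes x cells matrix."""
    sub = values[:, cells]
    n = cells.size
    csr = sp.csr_matrix(sub)
    k = np.diff(csr.indptr)  # positives per gene (stored values are > 0)
    s = np.asarray(csr.sum(axis=1)).ravel()
    sq = csr.copy()
    sq.data = sq.data**2
    ss = np.asarray(sq.sum(axis=1)).ravel()
    return n, k, s, ss


def _vectorized_lrt(values: sp.csr_matrix, cells_a, cells_b,
                    sigma_min=SIGMA_MIN):
    """Per-gene bimodal LRT stats for two cell sets; returns a DataFrame."""
    na, ka, sa, ssa = _matrix_group_stats(values, cells_a)
    nb, kb, sb, ssb = _matrix_group_stats(values, cells_b)
    n_genes = ka.size
    stat = np.empty(n_genes)
    p = np.empty(n_genes)
    df = np.empty(n_genes, dtype=int)
    for g in range(n_genes):
        stat[g], p[g], df[g] = _lrt_from_stats(
            na, ka[g], sa[g], ssa[g], nb, kb[g], sb[g], ssb[g], sigma_min
        )
    mean_a = sa / na
    mean_b = sb / nb
    return pd.DataFrame({
        "lrt_stat": stat,
        "p_value": p,
        "df": df,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "direction": np.sign(mean_a - mean_b).astype(int),
        "detect_frac_a": ka / na,
        "detect_frac_b": kb / nb,
    })


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * p.size / (np.arange(p.size) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(adj, 1.0)
        return out
    raise ValueError(f"unknown adjustment method {method!r}")


def markers_for_cluster(
    normalized: NormalizedMatrix,
    assignment: ClusterAssignment,
    cluster: int,
    min_frac: float = 0.1,
    alpha: float = 0.05,
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Markers of ``cluster``: overexpressed vs all other cells.

    Genes detected in >= ``min_frac`` of either group are tested with the
    bimodal LRT; p-values are adjusted over the tested genes
    (Bonferroni by default). The returned frame has one row per tested
    gene with an ``is_marker`` flag (adjusted p < alpha and positive
    direction), sorted by adjusted p then gene id.
    """
    if assignment.n_clusters < 2:
        raise ValueError("marker calling needs at least 2 clusters")
    in_cluster = assignment.cells_of(cluster)
    out_cluster = np.flatnonzero(assignment.final != cluster)
    if in_cluster.size == 0:
        raise ValueError(f"cluster {cluster} has no cells")
    if out_cluster.size == 0:
        raise ValueError("cluster covers all cells; nothing to compare")
    table = _vectorized_lrt(normalized.values, in_cluster, out_cluster)
    table.insert(0, "gene", normalized.gene_ids)
    tested = (table["detect_frac_a"] >= min_frac) | (
        table["detect_frac_b"] >= min_frac
    )
    table = table[tested].reset_index(drop=True)
    if table.empty:
        raise ValueError("no genes pass the detection prefilter")
    table["adjusted_p"] = _adjust(table["p_value"].to_numpy(), method)
    table["is_marker"] = (table["adjusted_p"] < alpha) & (table["direction"] > 0)
    table.insert(1, "cluster", cluster)
    return table.sort_values(
        ["adjusted_p", "gene"], kind="stable"
    ).reset_index(drop=True)


def all_markers(
    normalized: NormalizedMatrix,
    assignment: ClusterAssignment,
    min_frac: float = 0.1,
    alpha: float = 0.05,
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Concatenated marker tables for every final cluster."""
    frames = [
        markers_for_cluster(
            normalized, assignment, c, min_frac=min_frac, alpha=alpha,
            method=method,
        )
        for c in range(assignment.n_clusters)
    ]
    return pd.concat(frames, ignore_index=True)


def ranked_list(
    normalized: NormalizedMatrix,
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    descriptor: str = "",
) -> pd.DataFrame:
    """Genes ranked by signed -log10 p of the bimodal LRT (descending).

    The ranking statistic is direction * (-log10 p); ties resolve by LRT
    statistic, then gene id lexicographically. Returns a frame with columns
    gene, stat, lrt_stat, p_value, direction and a ``descriptor`` attribute
    column.
    """
    cells_a = np.asarray(cells_a)
    cells_b = np.asarray(cells_b)
    if cells_a.size == 0 or cells_b.size == 0:
        raise ValueError("both cell sets must be nonempty")
    table = _vectorized_lrt(normalized.values, cells_a, cells_b)
    p = np.maximum(table["p_value"].to_numpy(), np.finfo(float).tiny)
    stat = table["direction"].to_numpy() * (-np.log10(p))
    genes = np.array(normalized.gene_ids)
    # descending stat; ties by lrt_stat (desc), then gene id (asc)
    order = np.lexsort(
        (genes, -table["lrt_stat"].to_numpy(), -stat)
    )
    out = pd.DataFrame({
        "gene": genes[order],
        "stat": stat[order],
        "lrt_stat": table["lrt_stat"].to_numpy()[order],
        "p_value": table["p_value"].to_numpy()[order],
        "direction": table["direction"].to_numpy()[order],
        "descriptor": descriptor,
    })
    return out
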