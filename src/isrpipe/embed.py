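"""Depth normalization, dispersion-based variable-gene selection, and PCA.

The workflow is the standard one for droplet UMI data: per-barcode counts
are scaled to a common depth (default 1e4) and log1p-transformed; highly
variable genes are picked by z-scoring the dispersion (variance/mean on the
de-logged scale) within equal-occupancy mean-expression bins; the selected
genes are centered and unit-scaled per gene and the cells embedded with PCA
(default 50 components, full SVD below 5000 cells, seeded randomized SVD
above).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .containers import CountMatrix, NormalizedMatrix

__all__ = [
    "Embedding",
    "normalize_counts",
    "select_variable_genes",
    "compute_pca",
    "LogNormalizer",
    "VariableGeneSelector",
    "PCAEmbedder",
]

_FULL_SVD_MAX_CELLS = 5000


@dataclass
class Embedding:
    """PCA cell embedding: barcodes x n_pcs coordinates."""

    barcode_ids: list[str]
    coordinates: np.ndarray
    variance_explained: np.ndarray
    variable_genes: list[str]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedding coordinates contain non-finite values")
        if np.any(np.diff(self.variance_explained) > 1e-12):
            raise ValueError("variance_explained must be nonincreasing")

    @property
    def n_pcs(self) -> int:
        return self.coordinates.shape[1]


def normalize_counts(
    counts: CountMatrix, scale_factor: float = 1e4
) -> NormalizedMatrix:
    """Depth-normalize to ``scale_factor`` counts per barcode, then log1p."""
    totals = counts.barcode_totals()
    if (totals == 0).any():
        raise ValueError("zero-total barcode; run barcode filtering first")
    mat = counts.counts.tocsc().astype(np.float64)
    inv = sp.diags(scale_factor / totals)
    scaled = (mat @ inv).tocsr()
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(
        gene_ids=counts.gene_ids,
        barcode_ids=counts.barcode_ids,
        values=scaled,
    )


def _gene_mean_dispersion(values: sp.csr_matrix):
    """Per-gene mean and dispersion on the de-logged (expm1) scale."""
    x = values.copy()
    x.data = np.expm1(x.data)
    n = x.shape[1]
    mean = np.asarray(x.sum(axis=1)).ravel() / n
    sq = x.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.sum(axis=1)).ravel() / n
    var = np.maximum(ex2 - mean**2, 0.0) * (n / max(n - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    return mean, dispersion


def select_variable_genes(
    normalized: NormalizedMatrix,
    n_bins: int = 20,
    z_cutoff: float = 1.0,
    mean_bounds: tuple[float, float] = (0.0125, 8.0),
) -> list[str]:
    """Select genes with high within-bin dispersion z-score.

    Genes are binned by log-mean expression into ``n_bins`` equal-occupancy
    bins; the dispersion of each gene is z-scored against its bin. Genes
    with z >= ``z_cutoff`` and log-mean within ``mean_bounds`` are returned
    in input order.
    """
    mean, dispersion = _gene_mean_dispersion(normalized.values)
    log_mean = np.log1p(mean)
    expressed = mean > 0
    if expressed.sum() < n_bins:
        raise ValueError(
            f"only {int(expressed.sum())} expressed genes for {n_bins} bins; "
            "reduce n_bins"
        )
    order_stat = log_mean[expressed]
    # equal-occupancy binning by rank
    quantiles = np.quantile(order_stat, np.linspace(0, 1, n_bins + 1))
    quantiles[0] -= 1e-9
    bin_of = np.digitize(order_stat, quantiles[1:-1], right=True)

    z = np.zeros(mean.size)
    disp_expr = dispersion[expressed]
    z_expr = np.zeros(disp_expr.size)
    for b in range(n_bins):
        sel = bin_of == b
        if not sel.any():
            continue
        mu = disp_expr[sel].mean()
        sd = disp_expr[sel].std(ddof=1) if sel.sum() > 1 else 0.0
        if sd > 0:
            z_expr[sel] = (disp_expr[sel] - mu) / sd
    z[expressed] = z_expr

    lo, hi = mean_bounds
    keep = expressed & (z >= z_cutoff) & (log_mean >= lo) & (log_mean <= hi)
    genes = [g for g, k in zip(normalized.gene_ids, keep) if k]
    if not genes:
        raise ValueError(
            "no variable genes selected; relax z_cutoff or mean_bounds"
        )
    return genes


def compute_pca(
    normalized: NormalizedMatrix,
    variable_genes: list[str],
    n_pcs: int = 50,
    random_state: int = 0,
) -> Embedding:
    """PCA of cells on the centered, unit-scaled variable genes.

    Zero-variance genes are dropped with a warning. Components are ordered
    by explained variance; the deterministic full SVD solver is used below
    5000 cells, seeded randomized SVD above.
    """
    idx = normalized.gene_index(variable_genes)
    X = np.asarray(normalized.values[idx, :].todense()).T  # cells x genes
    n_cells = X.shape[0]
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    usable = sd > 0
    if not usable.all():
        warnings.warn(
            f"dropping {int((~usable).sum())} zero-variance gene(s) before PCA"
        )
    X = (X[:, usable] - mu[usable]) / sd[usable]
    used_genes = [g for g, u in zip(variable_genes, usable) if u]
    if len(used_genes) < 2:
        raise ValueError("fewer than 2 usable genes for PCA")
    max_pcs = min(len(used_genes), n_cells - 1)
    k = min(n_pcs, max_pcs)
    solver = "full" if n_cells <= _FULL_SVD_MAX_CELLS else "randomized"
    pca = PCA(n_components=k, svd_solver=solver, random_state=random_state)
    coords = pca.fit_transform(X)
    return Embedding(
        barcode_ids=normalized.barcode_ids,
        coordinates=coords,
        variance_explained=pca.explained_variance_ratio_,
        variable_genes=used_genes,
    )


class LogNormalizer(BaseEstimator):
    """Stateless depth normalization transformer (CountMatrix in/out)."""

    def __init__(self, scale_factor: float = 1e4):
        self.scale_factor = scale_factor

    def fit(self, X: CountMatrix, y=None):
        return self

    def transform(self, X: CountMatrix) -> NormalizedMatrix:
        return normalize_counts(X, scale_factor=self.scale_factor)

    def fit_transform(self, X: CountMatrix, y=None) -> NormalizedMatrix:
        return self.transform(X)


class VariableGeneSelector(BaseEstimator):
    """Dispersion-based gene selector; ``variable_genes_`` after fit."""

    def __init__(self, n_bins: int = 20, z_cutoff: float = 1.0,
                 mean_bounds: tuple[float, float] = (0.0125, 8.0)):
        self.n_bins = n_bins
        self.z_cutoff = z_cutoff
        self.mean_bounds = mean_bounds

    def fit(self, X: NormalizedMatrix, y=None):
        self.variable_genes_ = select_variable_genes(
            X, n_bins=self.n_bins, z_cutoff=self.z_cutoff,
            mean_bounds=self.mean_bounds,
        )
        return self

    def transform(self, X: NormalizedMatrix) -> NormalizedMatrix:
        idx = X.gene_index(self.variable_genes_)
        return NormalizedMatrix(
            gene_ids=self.variable_genes_,
            barcode_ids=X.barcode_ids,
            values=X.values[idx, :],
        )


class PCAEmbedder(BaseEstimator):
    """Variable-gene PCA embedder; ``embedding_`` after fit."""

    def __init__(self, n_pcs: int = 50, random_state: int = 0,
                 variable_genes: list[str] | None = None):
        self.n_pcs = n_pcs
        self.random_state = random_state
        self.variable_genes = variable_genes

    def fit(self, X: NormalizedMatrix, y=None):
        genes = self.variable_genes or X.gene_ids
        self.embedding_ = compute_pca(
            X, genes, n_pcs=self.n_pcs, random_state=self.random_state
        )
        return self

    def transform(self, X: NormalizedMatrix) -> np.ndarray:
        self.fit(X)
        return self.embedding_.coordinates

    def fit_transform(self, X: NormalizedMatrix, y=None) -> np.ndarray:
        self.fit(X)
        return self.embedding_.coordinates
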