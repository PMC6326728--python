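"""Bulk-transcriptome SVD eigengene decomposition and gene-class extraction.

A genes x samples expression matrix (TPM) is optionally ln(x+1)-transformed
and per-gene centered, then factored X = U S V^T by exact SVD. The right
singular vectors (rows of V^T) are the eigengenes: canonical expression
patterns across samples. The fraction of variance captured by component k
is s_k^2 / sum s^2. Gene classes on a component are genes whose loading
(column k of U) exceeds, in absolute value, two-fold the mean absolute
loading of that component, split by sign; on a genotype-contrast design the
first component's classes recover the up- and down-regulated programs.

Sign convention: each component is flipped so that the sample-pattern entry
of largest magnitude is nonnegative, making loadings reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "EigengeneDecomposition",
    "GeneClassResult",
    "svd_decompose",
    "gene_classes",
    "scree",
    "project_samples",
    "EigengeneSVD",
]


@dataclass
class EigengeneDecomposition:
    """SVD factors of a (possibly transformed) expression matrix."""

    gene_ids: list[str]
    sample_ids: list[str]
    gene_loadings: np.ndarray   # genes x components (U)
    singular_values: np.ndarray
    eigengenes: np.ndarray      # components x samples (V^T rows)
    variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        s = self.singular_values
        if np.any(np.diff(s) > 1e-9 * max(s[0], 1.0)):
            raise ValueError("singular values must be nonincreasing")

    @property
    def n_components(self) -> int:
        return self.singular_values.size


@dataclass
class GeneClassResult:
    component: int
    threshold: float
    up_genes: list[str]
    down_genes: list[str]


def svd_decompose(
    expression: pd.DataFrame | np.ndarray,
    log_transform: bool = True,
    center: bool = True,
    gene_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> EigengeneDecomposition:
    """Exact SVD of a genes x samples matrix with optional ln(x+1)/centering."""
    if isinstance(expression, pd.DataFrame):
        gene_ids = list(expression.index.astype(str))
        sample_ids = list(expression.columns.astype(str))
        X = expression.to_numpy(dtype=float)
    else:
        X = np.asarray(expression, dtype=float)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(X.shape[0])]
        if sample_ids is None:
            sample_ids = [f"s{j}" for j in range(X.shape[1])]
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("expression matrix contains non-finite entries")
    if log_transform:
        if X.min() < 0:
            raise ValueError("log transform requires nonnegative input")
        X = np.log1p(X)
    if center:
        X = X - X.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # flip each component so the largest-|.| sample entry is nonnegative
    for k in range(s.size):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    total = (s**2).sum()
    var_frac = s**2 / total if total > 0 else np.zeros_like(s)
    return EigengeneDecomposition(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        gene_loadings=u,
        singular_values=s,
        eigengenes=vt,
        variance_fraction=var_frac,
    )


def gene_classes(
    decomposition: EigengeneDecomposition, component: int = 0
) -> GeneClassResult:
    """Split genes by the two-fold-mean absolute-loading threshold.

    threshold = 2 * mean(|loading|) on the chosen component; the up class
    holds genes with loading > +threshold, the down class loading <
    -threshold.
    """
    if not 0 <= component < decomposition.n_components:
        raise IndexError(f"component {component} out of range")
    loadings = decomposition.gene_loadings[:, component]
    threshold = 2.0 * np.mean(np.abs(loadings))
    genes = np.array(decomposition.gene_ids)
    return GeneClassResult(
        component=component,
        threshold=float(threshold),
        up_genes=list(genes[loadings > threshold]),
        down_genes=list(genes[loadings < -threshold]),
    )


def scree(decomposition: EigengeneDecomposition) -> np.ndarray:
    """Ordered variance fractions s_k^2 / sum s^2."""
    return decomposition.variance_fraction.copy()


def project_samples(
    decomposition: EigengeneDecomposition, components=(0, 1)
) -> pd.DataFrame:
    """Per-sample coordinates s_k * V_k on the requested components."""
    comps = list(components)
    for k in comps:
        if not 0 <= k < decomposition.n_components:
            raise IndexError(f"component {k} out of range")
    coords = {
        f"component_{k + 1}":
            decomposition.singular_values[k] * decomposition.eigengenes[k]
        for k in comps
    }
    return pd.DataFrame(coords, index=decomposition.sample_ids)


class EigengeneSVD(BaseEstimator):
    """Estimator wrapper around the eigengene decomposition.

    ``fit`` takes a genes x samples frame or array; the decomposition is
    available as ``decomposition_`` and the sample projection via
    ``transform``.
    """

    def __init__(self, log_transform: bool = True, center: bool = True):
        self.log_transform = log_transform
        self.center = center

    def fit(self, X, y=None):
        self.decomposition_ = svd_decompose(
            X, log_transform=self.log_transform, center=self.center
        )
        return self

    def transform(self, X=None, components=(0, 1)) -> pd.DataFrame:
        return project_samples(self.decomposition_, components)

    def fit_transform(self, X, y=None, components=(0, 1)) -> pd.DataFrame:
        return self.fit(X).transform(components=components)

    def gene_classes(self, component: int = 0) -> GeneClassResult:
        return gene_classes(self.decomposition_, component)
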