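"""Marker-based cluster cell-type assignment.

Each cluster receives a raw score per candidate cell type: for every marker
of the type detected in the cluster (count > 0 in at least one cell, or a
configurable minimum fraction), the marker's mean normalized expression
over ALL cells of the cluster is multiplied by the fraction of cells it is
detected in; the gene scores are summed and divided by the type's total
marker count (detected or not), a correction for ascertainment differences
between reference types. Raw scores are scaled to sum to one across types,
giving a probability vector; the cluster is assigned the argmax type when
its probability exceeds 0.5 (strictly), otherwise it is UNASSIGNED.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import MarkerReference, NormalizedMatrix
from .cluster import ClusterAssignment

__all__ = [
    "UNASSIGNED",
    "CellTypeProbabilities",
    "score_cluster",
    "assign_all",
    "CellTypeScorer",
]

UNASSIGNED = "UNASSIGNED"


@dataclass
class CellTypeProbabilities:
    """Per-cluster cell-type scores, probabilities and assignment."""

    cluster: str
    raw_scores: dict[str, float]
    probabilities: dict[str, float]
    assignment: str
    threshold: float = 0.5

    def as_row(self) -> dict:
        row = {"cluster": self.cluster, "assignment": self.assignment}
        for t, s in self.raw_scores.items():
            row[f"score_{t}"] = s
        for t, p in self.probabilities.items():
            row[f"prob_{t}"] = p
        return row


def score_cluster(
    normalized: NormalizedMatrix,
    cluster_cells: np.ndarray,
    reference: MarkerReference,
    cluster_label: str = "0",
    threshold: float = 0.5,
    min_detect_frac: float = 0.0,
) -> CellTypeProbabilities:
    """Score one cluster against every reference cell type.

    A marker counts as expressed in the cluster when its detection fraction
    exceeds ``min_detect_frac`` (default 0: detected in at least one cell).
    """
    cluster_cells = np.asarray(cluster_cells)
    if cluster_cells.size == 0:
        raise ValueError("cluster has no cells")
    if len(reference) == 0:
        raise ValueError("marker reference is empty")
    gene_lookup = {g: i for i, g in enumerate(normalized.gene_ids)}
    if not any(
        g in gene_lookup for genes in reference.markers.values() for g in genes
    ):
        raise ValueError("no marker of any cell type is in the gene universe")

    sub = normalized.values[:, cluster_cells]
    n = cluster_cells.size
    mean_expr = np.asarray(sub.sum(axis=1)).ravel() / n
    detect_frac = np.asarray((sub > 0).sum(axis=1)).ravel() / n

    raw: dict[str, float] = {}
    for cell_type, genes in reference.markers.items():
        total = 0.0
        for g in genes:
            i = gene_lookup.get(g)
            if i is None:
                continue
            frac = detect_frac[i]
            expressed = frac > min_detect_frac if min_detect_frac > 0 else frac > 0
            if expressed:
                total += mean_expr[i] * frac
        raw[cell_type] = total / len(genes)

    score_sum = sum(raw.values())
    if score_sum > 0:
        probs = {t: s / score_sum for t, s in raw.items()}
        best = max(probs, key=lambda t: (probs[t], t))
        assignment = best if probs[best] > threshold else UNASSIGNED
    else:
        probs = {t: float("nan") for t in raw}
        assignment = UNASSIGNED
    return CellTypeProbabilities(
        cluster=cluster_label,
        raw_scores=raw,
        probabilities=probs,
        assignment=assignment,
        threshold=threshold,
    )


def assign_all(
    normalized: NormalizedMatrix,
    assignment: ClusterAssignment,
    reference: MarkerReference,
    threshold: float = 0.5,
    min_detect_frac: float = 0.0,
) -> pd.DataFrame:
    """Score every final leaf cluster; one row per cluster."""
    leaf_names = assignment.leaf_labels
    rows = []
    for c in range(assignment.n_clusters):
        res = score_cluster(
            normalized,
            assignment.cells_of(c),
            reference,
            cluster_label=leaf_names[c],
            threshold=threshold,
            min_detect_frac=min_detect_frac,
        )
        rows.append(res.as_row())
    return pd.DataFrame(rows)


class CellTypeScorer(BaseEstimator):
    """Estimator wrapper: fit stores the reference, predict labels clusters."""

    def __init__(self, reference: MarkerReference | None = None,
                 threshold: float = 0.5, min_detect_frac: float = 0.0):
        self.reference = reference
        self.threshold = threshold
        self.min_detect_frac = min_detect_frac

    def fit(self, X=None, y=None):
        if self.reference is None:
            raise ValueError("a MarkerReference is required")
        return self

    def predict(self, normalized: NormalizedMatrix,
                assignment: ClusterAssignment) -> pd.DataFrame:
        self.fit()
        self.table_ = assign_all(
            normalized, assignment, self.reference,
            threshold=self.threshold, min_detect_frac=self.min_detect_frac,
        )
        return self.table_
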