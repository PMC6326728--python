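"""Shared in-memory containers for the pipeline.

The single-cell stages pass around two matrix containers, both oriented
genes x barcodes (the 10x on-disk convention): :class:`CountMatrix` holds raw
UMI counts, :class:`NormalizedMatrix` holds depth-normalized log expression.
Gene sets and cell-type marker references are small mapping containers with
validation on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "GeneSetCollection",
    "MarkerReference",
]


def _check_unique(ids: list[str], axis: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {axis} id: {dup!r}")


@dataclass
class CountMatrix:
    """Sparse UMI count matrix, genes x barcodes.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per matrix row.
    barcode_ids
        Unique droplet barcodes, one per matrix column.
    counts
        Nonnegative integer sparse matrix of shape
        ``(len(gene_ids), len(barcode_ids))``, in UMI units.
    """

    gene_ids: list[str]
    barcode_ids: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.barcode_ids = list(self.barcode_ids)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.barcode_ids, "barcode")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.barcode_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcode_ids)} barcodes"
            )
        if self.counts.nnz:
            data = self.counts.data
            if data.min() < 0:
                raise ValueError("counts must be nonnegative")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integers")
            self.counts.data = np.asarray(np.round(data), dtype=np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_barcodes(self) -> int:
        return len(self.barcode_ids)

    def barcode_totals(self) -> np.ndarray:
        """Total UMI count per barcode."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_barcodes(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            gene_ids=self.gene_ids,
            barcode_ids=[self.barcode_ids[i] for i in idx],
            counts=self.counts[:, idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.barcode_ids == other.barcode_ids
            and (self.counts != other.counts).nnz == 0
        )


@dataclass
class NormalizedMatrix:
    """Log-scale normalized expression, genes x barcodes (sparse).

    Values are ``log1p(count / barcode_total * scale_factor)``; zeros stay
    zero so the matrix remains sparse.
    """

    gene_ids: list[str]
    barcode_ids: list[str]
    values: sp.csr_matrix

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.barcode_ids = list(self.barcode_ids)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.barcode_ids, "barcode")
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.barcode_ids)):
            raise ValueError("values shape does not match id lists")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("normalized values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_barcodes(self) -> int:
        return len(self.barcode_ids)

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> gene list, plus descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


@dataclass
class MarkerReference:
    """Cell-type marker reference: cell-type name -> marker gene ids."""

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        _check_unique(list(self.markers), "cell-type")
        for ct, genes in self.markers.items():
            if not genes:
                raise ValueError(f"cell type {ct!r} has no markers")

    @property
    def cell_types(self) -> list[str]:
        return list(self.markers)

    def __getitem__(self, cell_type: str) -> list[str]:
        return self.markers[cell_type]

    def __len__(self) -> int:
        return len(self.markers)
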