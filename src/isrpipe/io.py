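"""Readers and writers for the standard on-disk formats.

10x-style triples (MatrixMarket ``matrix.mtx`` + ``barcodes.tsv`` +
``features.tsv``), GMT gene-set files, cell-type marker reference TSVs and
bulk genes x samples TSV matrices. All readers accept optionally gzipped
text files. Round-tripping through a writer/reader pair is lossless.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, GeneSetCollection, MarkerReference

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_id_lines(path) -> list[str]:
    with _open_text(path) as fh:
        # features.tsv may carry extra columns (gene symbol, feature type);
        # the first field is the id.
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts_10x(matrix_path, barcodes_path, features_path) -> CountMatrix:
    """Read a 10x triple into a genes x barcodes :class:`CountMatrix`.

    The on-disk matrix may be stored either genes x barcodes or
    barcodes x genes; orientation is resolved by matching the MTX dimensions
    against the lengths of the two id files.
    """
    mat = sp.csr_matrix(scipy.io.mmread(matrix_path))
    features = _read_id_lines(features_path)
    barcodes = _read_id_lines(barcodes_path)
    n_rows, n_cols = mat.shape
    if n_rows == len(features) and n_cols == len(barcodes):
        pass
    elif n_rows == len(barcodes) and n_cols == len(features):
        mat = sp.csr_matrix(mat.T)
    else:
        raise FormatError(
            f"matrix dimensions {mat.shape} match neither "
            f"{len(features)} features x {len(barcodes)} barcodes "
            f"nor the transpose"
        )
    try:
        return CountMatrix(gene_ids=features, barcode_ids=barcodes, counts=mat)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_counts_10x(counts: CountMatrix, out_dir) -> dict[str, Path]:
    """Write ``matrix.mtx``, ``barcodes.tsv`` and ``features.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "barcodes": out_dir / "barcodes.tsv",
        "features": out_dir / "features.tsv",
    }
    scipy.io.mmwrite(
        paths["matrix"], sp.coo_matrix(counts.counts), field="integer"
    )
    paths["barcodes"].write_text("".join(b + "\n" for b in counts.barcode_ids))
    paths["features"].write_text("".join(g + "\n" for g in counts.gene_ids))
    return paths


def read_gene_sets_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are dropped (first occurrence kept) with a
    logged warning.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning(
                    "%s: line %d: set %r has %d duplicate gene entries",
                    path, lineno, name, len(genes) - len(deduped),
                )
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets_gmt(collection: GeneSetCollection, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")
    return path


def read_marker_reference(path) -> MarkerReference:
    """Read a marker reference TSV with columns ``cell_type`` and ``gene``."""
    df = pd.read_csv(path, sep="\t")
    if not {"cell_type", "gene"}.issubset(df.columns):
        raise FormatError(
            f"{path}: marker reference needs columns 'cell_type' and 'gene'"
        )
    markers = {
        str(ct): [str(g) for g in grp["gene"]]
        for ct, grp in df.groupby("cell_type", sort=False)
    }
    return MarkerReference(markers=markers)


def write_marker_reference(ref: MarkerReference, path) -> Path:
    rows = [(ct, g) for ct, genes in ref.markers.items() for g in genes]
    pd.DataFrame(rows, columns=["cell_type", "gene"]).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


def read_bulk_matrix(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene ids")
    return df


def write_bulk_matrix(df: pd.DataFrame, path) -> Path:
    df.to_csv(path, sep="\t", float_format="%.6g")
    return Path(path)


def write_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    """Write a result table as TSV with 6 significant digits for floats."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
    return Path(path)
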