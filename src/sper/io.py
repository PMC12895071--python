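"""Readers and writers for the external formats the pipeline consumes.

Supported formats
-----------------
* Expression: MatrixMarket coordinate triplets (10x convention: rows = genes,
  columns = spots) with companion one-per-line gene / barcode files, or a
  dense TSV with spots as rows and a header of gene names.
* Geometry: Visium-style positions table (barcode, in_tissue, array row/col,
  pixel row/col; no header) plus a micrometers-per-pixel scale factor, or a
  plain ``id<TAB>x<TAB>y`` TSV already in micrometers.
* Compositions / prevalence / scores: labeled TSV matrices.
* Gene sets: UTF-8, one gene per line. Ligand-receptor pairs: two-column TSV
  with header ``ligand<TAB>receptor``.

Writers emit plain text; ``write_scores`` adds a JSON run-metadata sidecar.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    CompositionMatrix,
    ExpressionMatrix,
    GeneSet,
    LigandReceptorTable,
    PrevalenceMatrix,
    SpotGeometry,
)

logger = logging.getLogger(__name__)


def _read_lines(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [ln.split("\t")[0].strip() for ln in fh if ln.strip()]


def read_expression(
    path,
    genes_path=None,
    barcodes_path=None,
    dialect: str = "auto",
) -> ExpressionMatrix:
    """Read a counts-oriented expression matrix (spots x genes).

    ``dialect='mtx'`` expects a MatrixMarket file whose rows are genes and
    columns are spots (the 10x convention) plus companion gene / barcode
    lists; ``dialect='tsv'`` a dense matrix with spot rows and a gene header.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "mtx" if path.suffix == ".mtx" else "tsv"
    if dialect == "mtx":
        if genes_path is None or barcodes_path is None:
            raise ValueError("MTX dialect needs companion gene and barcode files")
        mat = scipy.io.mmread(path)
        mat = scipy.sparse.coo_matrix(mat).toarray()
        genes = _read_lines(genes_path)
        barcodes = _read_lines(barcodes_path)
        if mat.shape != (len(genes), len(barcodes)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match companion lists "
                f"({len(genes)} genes, {len(barcodes)} barcodes)"
            )
        return ExpressionMatrix(barcodes, genes, mat.T.astype(float))
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return ExpressionMatrix(df.index, df.columns, df.to_numpy(dtype=float))
    raise ValueError(f"unknown expression dialect {dialect!r}")


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t")


def write_expression_mtx(expr: ExpressionMatrix, mtx_path, genes_path, barcodes_path) -> None:
    """Write genes x spots MatrixMarket triplets plus companion lists."""
    sparse = scipy.sparse.coo_matrix(expr.values.T)
    scipy.io.mmwrite(str(mtx_path), sparse)
    Path(genes_path).write_text("\n".join(expr.gene_ids) + "\n", encoding="utf-8")
    Path(barcodes_path).write_text("\n".join(expr.spot_ids) + "\n", encoding="utf-8")


def normalize_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each gene column by its global mean over all spots.

    All-zero genes stay zero (0/0 := 0) so gene indices remain stable;
    idempotent on its own output because normalized columns have mean 1.
    """
    means = expr.values.mean(axis=0)
    safe = np.where(means > 0, means, 1.0)
    values = expr.values / safe[np.newaxis, :]
    return ExpressionMatrix(expr.spot_ids, expr.gene_ids, values, normalized=True)


def read_geometry(
    positions_path,
    scale: float | None = None,
    dialect: str = "auto",
    spacing: float | None = None,
) -> SpotGeometry:
    """Read spot coordinates in micrometers.

    Visium dialect: 6-column positions CSV (barcode, in_tissue, array_row,
    array_col, pxl_row, pxl_col) without header; ``scale`` is the
    micrometers-per-pixel factor (e.g. from a scale-factor JSON's
    ``microns_per_pixel``, or 65 / ``spot_diameter_fullres`` for a 65 um
    Visium spot). Out-of-tissue rows are dropped. Plain dialect: a TSV with
    header ``id, x, y`` already in micrometers; coordinates pass through.
    """
    positions_path = Path(positions_path)
    if dialect == "auto":
        dialect = "visium" if positions_path.suffix == ".csv" else "plain"
    if dialect == "visium":
        if scale is None:
            raise ValueError("visium dialect requires a micrometers-per-pixel scale")
        df = pd.read_csv(positions_path, header=None)
        if df.shape[1] < 6:
            raise ValueError("visium positions table needs 6 columns")
        df.columns = ["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"][
            : df.shape[1]
        ]
        df = df[df["in_tissue"].astype(int) == 1]
        coords = df[["pxl_col", "pxl_row"]].to_numpy(dtype=float) * float(scale)
        return SpotGeometry(df["barcode"], coords, spacing=spacing)
    if dialect == "plain":
        df = pd.read_csv(positions_path, sep="\t")
        coords = df.iloc[:, 1:3].to_numpy(dtype=float)
        return SpotGeometry(df.iloc[:, 0], coords, spacing=spacing)
    raise ValueError(f"unknown geometry dialect {dialect!r}")


def write_geometry_tsv(geometry: SpotGeometry, path) -> None:
    pd.DataFrame(
        {"spot": geometry.spot_ids, "x_um": geometry.coordinates[:, 0], "y_um": geometry.coordinates[:, 1]}
    ).to_csv(path, sep="\t", index=False)


def read_compositions(path) -> CompositionMatrix:
    """Read a cell-type x spot composition TSV (types as rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CompositionMatrix(df.index, df.columns, df.to_numpy(dtype=float))


def write_compositions(comp: CompositionMatrix, path) -> None:
    comp.to_frame().to_csv(path, sep="\t")


def read_prevalence(path) -> PrevalenceMatrix:
    """Read a cell-type x gene expression-prevalence TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PrevalenceMatrix(df.index, df.columns, df.to_numpy(dtype=float))


def write_prevalence(prev: PrevalenceMatrix, path) -> None:
    prev.to_frame().to_csv(path, sep="\t")


def read_gene_set(path, name: str | None = None) -> GeneSet:
    genes = _read_lines(path)
    return GeneSet(name or Path(path).stem, frozenset(genes))


def read_lr_table(path) -> LigandReceptorTable:
    df = pd.read_csv(path, sep="\t")
    if not {"ligand", "receptor"} <= set(df.columns):
        raise ValueError("ligand-receptor table needs a 'ligand<TAB>receptor' header")
    return LigandReceptorTable(df[["ligand", "receptor"]])


def write_lr_table(table: LigandReceptorTable, path) -> None:
    table.pairs.to_csv(path, sep="\t", index=False)


def write_scores(scores: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a cell-type x gene score TSV plus a JSON run-metadata sidecar."""
    path = Path(path)
    scores.to_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    payload = dict(metadata or {})
    payload.setdefault("n_cell_types", scores.shape[0])
    payload.setdefault("n_genes", scores.shape[1])
    sidecar.write_text(json.dumps(payload, indent=2, default=str), encoding="utf-8")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
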