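"""Read/write the on-disk dataset: Matrix-Market counts plus TSV sidecars.

Layout of a dataset directory (10x-style, all plain text, optional .gz):

* ``matrix.mtx``   — Matrix-Market coordinate integer matrix; a header
  comment declares the orientation (``cells x genes`` or ``genes x cells``)
* ``features.tsv`` — gene annotation (gene_id, symbol, origin, chromosome,
  arm, start, functional_class, temporal_class)
* ``barcodes.tsv`` — one barcode per data line
* ``cells.tsv``    — cell metadata (barcode, sample, status, assigned_type,
  cluster); infection status falls back to the "v"-suffix sample-name
  convention when the status column is absent

A marker database is a separate TSV with columns
``cell_type, direction (pos|neg), symbol``.
"""

from __future__ import annotations

import gzip
import io
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from virocell.datatypes import CELL_COLUMNS, GENE_COLUMNS, ExpressionMatrix, MarkerDB
from virocell.errors import FormatError, ValidationError

_ORIENT_COMMENT = "orientation: cells x genes"


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(path: Path, stem: str) -> Path:
    for cand in (path / stem, path / (stem + ".gz")):
        if cand.exists():
            return cand
    raise FormatError(f"missing file {stem} in {path}")


def write_dataset(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write a dataset directory (matrix.mtx + TSV sidecars)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    coo = matrix.counts.tocoo()
    buf = io.BytesIO()
    scipy.io.mmwrite(
        buf, coo, comment=_ORIENT_COMMENT, field="integer"
    )
    (path / "matrix.mtx").write_bytes(buf.getvalue())

    genes = matrix.genes.reset_index()
    genes.columns = ["gene_id"] + list(GENE_COLUMNS)
    genes.to_csv(path / "features.tsv", sep="\t", index=False)

    pd.DataFrame({"barcode": matrix.barcodes}).to_csv(
        path / "barcodes.tsv", sep="\t", index=False
    )

    cells = matrix.cells.reset_index()
    cells.columns = ["barcode"] + list(CELL_COLUMNS)
    cells.to_csv(path / "cells.tsv", sep="\t", index=False)


def read_dataset(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a dataset directory into a validated :class:`ExpressionMatrix`."""
    path = Path(path)
    mtx_path = _find(path, "matrix.mtx")

    with _open_maybe_gz(mtx_path, "rt") as fh:
        text = fh.read()
    genes_first = _genes_first_orientation(text)
    try:
        mat = scipy.io.mmread(io.StringIO(text))
    except Exception as exc:  # malformed coordinate data
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        bad = int(np.flatnonzero(~np.isclose(mat.data, np.round(mat.data)))[0])
        raise FormatError(
            f"{mtx_path}: non-integer entry at data line {bad + 1}"
        )

    genes = pd.read_csv(_find(path, "features.tsv"), sep="\t", dtype={"gene_id": str})
    if "gene_id" not in genes.columns:
        raise FormatError("features.tsv must have a gene_id column")
    genes = genes.set_index("gene_id")
    for col in GENE_COLUMNS:
        if col not in genes.columns:
            genes[col] = None
    genes = genes[list(GENE_COLUMNS)]
    # pandas reads empty optional fields as NaN; normalise to None
    genes = genes.astype(object).where(pd.notna(genes), None)
    genes["start"] = genes["start"].astype(int)

    barcodes = pd.read_csv(_find(path, "barcodes.tsv"), sep="\t", dtype=str)
    if "barcode" not in barcodes.columns:
        raise FormatError("barcodes.tsv must have a barcode column")
    dup = barcodes["barcode"][barcodes["barcode"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate barcode: {dup.iloc[0]!r}")

    cells = pd.read_csv(_find(path, "cells.tsv"), sep="\t", dtype={"barcode": str})
    cells = cells.set_index("barcode")
    if "sample" not in cells.columns:
        raise FormatError("cells.tsv must have a sample column")
    if "status" not in cells.columns or cells["status"].isna().all():
        # fallback: the "v"-suffix sample-name convention marks infected samples
        cells["status"] = [
            "infected" if str(s).endswith("v") else "control"
            for s in cells["sample"]
        ]
    for col in ("assigned_type", "cluster"):
        if col not in cells.columns:
            cells[col] = None
    cells = cells[list(CELL_COLUMNS)]
    cells = cells.astype(object).where(pd.notna(cells), None)

    if genes_first:
        mat = mat.T
    n_cells, n_genes = mat.shape
    if n_genes != len(genes):
        raise FormatError(
            f"matrix.mtx declares {n_genes} genes but features.tsv lists {len(genes)}"
        )
    if n_cells != len(barcodes):
        raise FormatError(
            f"matrix.mtx declares {n_cells} cells but barcodes.tsv lists {len(barcodes)}"
        )
    if list(cells.index) != list(barcodes["barcode"]):
        raise FormatError("cells.tsv barcodes do not match barcodes.tsv")

    try:
        return ExpressionMatrix(mat.tocsr(), genes, cells)
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def _genes_first_orientation(mtx_text: str) -> bool:
    """True when the Matrix-Market file stores genes in rows (10x layout)."""
    for line in mtx_text.splitlines():
        if line.startswith("%"):
            if "orientation" in line and "cells x genes" in line:
                return False
            if "orientation" in line and "genes x cells" in line:
                return True
            continue
        break
    # no declaration: assume the classic 10x genes x cells layout
    return True


def read_marker_db(path: str | os.PathLike) -> MarkerDB:
    """Read a marker database TSV (cell_type, direction, symbol)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_type", "direction", "symbol"}
    if not required <= set(df.columns):
        raise FormatError(
            f"marker table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    bad_dir = set(df["direction"]) - {"pos", "neg"}
    if bad_dir:
        raise FormatError(f"marker direction must be pos or neg, got {sorted(bad_dir)}")
    pos: dict[str, set[str]] = {}
    neg: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        target = pos if row["direction"] == "pos" else neg
        target.setdefault(row["cell_type"], set()).add(row["symbol"].upper())
    return MarkerDB(positive=pos, negative=neg)


def write_marker_db(db: MarkerDB, path: str | os.PathLike) -> None:
    rows = []
    for t in db.cell_types:
        for s in sorted(db.positive.get(t, ())):
            rows.append((t, "pos", s))
        for s in sorted(db.negative.get(t, ())):
            rows.append((t, "neg", s))
    pd.DataFrame(rows, columns=["cell_type", "direction", "symbol"]).to_csv(
        path, sep="\t", index=False
    )
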