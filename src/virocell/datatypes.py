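"""Core in-memory containers for the hybrid host+virus single-cell dataset.

The single source of truth for every analysis stage is an
:class:`ExpressionMatrix`: a sparse cells x genes integer count matrix with
two sidecar tables, one row per gene (:class:`GeneRecord` fields) and one
row per cell (:class:`CellRecord` fields). Host and viral genes live in the
same matrix; viral genes sit on a reserved virus contig, mirroring an
alignment against a human reference extended with the viral genome as an
extra chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from virocell.errors import ValidationError

#: Reserved contig name for viral genes.
VIRUS_CONTIG = "VV"

#: Poxvirus temporal expression classes (viral genes only).
TEMPORAL_CLASSES = ("Early", "Late", "EarlyLate", "Unknown")

GENE_COLUMNS = [
    "symbol",
    "origin",
    "chromosome",
    "arm",
    "start",
    "functional_class",
    "temporal_class",
]

CELL_COLUMNS = ["sample", "status", "assigned_type", "cluster"]


@dataclass(frozen=True)
class GeneRecord:
    """Annotation for a single gene in the hybrid gene universe."""

    gene_id: str
    symbol: str
    origin: str  # "host" | "viral"
    chromosome: str
    arm: str
    start: int  # 0-based
    functional_class: str | None = None
    temporal_class: str | None = None  # viral genes only

    def __post_init__(self) -> None:
        if self.origin not in ("host", "viral"):
            raise ValidationError(f"gene {self.gene_id}: origin must be host or viral")
        if self.origin == "viral":
            if self.chromosome != VIRUS_CONTIG:
                raise ValidationError(
                    f"gene {self.gene_id}: viral genes must sit on contig {VIRUS_CONTIG!r}"
                )
            if self.temporal_class not in TEMPORAL_CLASSES:
                raise ValidationError(
                    f"gene {self.gene_id}: viral gene needs a temporal class"
                )
        elif self.temporal_class is not None:
            raise ValidationError(
                f"gene {self.gene_id}: host genes carry no temporal class"
            )
        if self.start < 0:
            raise ValidationError(f"gene {self.gene_id}: start must be >= 0")


@dataclass(frozen=True)
class CellRecord:
    """Per-cell metadata: sample of origin, infection status, labels."""

    barcode: str
    sample: str
    status: str  # "infected" | "control"
    assigned_type: str | None = None
    cluster: int | None = None

    def __post_init__(self) -> None:
        if self.status not in ("infected", "control"):
            raise ValidationError(
                f"cell {self.barcode}: status must be infected or control"
            )


class ExpressionMatrix:
    """Sparse cells x genes count matrix with gene and cell sidecar tables.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells in rows, genes in columns.
    genes
        DataFrame indexed by unique gene id with columns
        ``symbol, origin, chromosome, arm, start, functional_class,
        temporal_class``.
    cells
        DataFrame indexed by unique barcode with columns
        ``sample, status, assigned_type, cluster``.
    """

    def __init__(self, counts, genes: pd.DataFrame, cells: pd.DataFrame) -> None:
        counts = sp.csr_matrix(counts)
        if counts.shape != (len(cells), len(genes)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(cells)} cells x {len(genes)} genes"
            )
        if counts.nnz and counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")
        if (
            counts.nnz
            and not np.issubdtype(counts.dtype, np.integer)
            and not np.array_equal(counts.data, np.round(counts.data))
        ):
            raise ValidationError("counts must be integers")
        if not cells.index.is_unique:
            dup = cells.index[cells.index.duplicated()][0]
            raise ValidationError(f"duplicate barcode: {dup!r}")
        if not genes.index.is_unique:
            dup = genes.index[genes.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        missing = [c for c in GENE_COLUMNS if c not in genes.columns]
        if missing:
            raise ValidationError(f"gene table missing columns: {missing}")
        missing = [c for c in CELL_COLUMNS if c not in cells.columns]
        if missing:
            raise ValidationError(f"cell table missing columns: {missing}")
        bad = set(cells["status"]) - {"infected", "control"}
        if bad:
            raise ValidationError(f"invalid infection status values: {sorted(bad)}")
        # status must be consistent within each sample
        per_sample = cells.groupby("sample", sort=False)["status"].nunique()
        mixed = per_sample[per_sample > 1]
        if len(mixed):
            raise ValidationError(
                f"samples with mixed infection status: {list(mixed.index)}"
            )
        self.counts = counts.astype(np.int64)
        self.genes = genes
        self.cells = cells

    # -- basic views ---------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def barcodes(self) -> pd.Index:
        return self.cells.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def viral_mask(self) -> np.ndarray:
        """Boolean mask over genes, True for viral genes."""
        return (self.genes["origin"] == "viral").to_numpy()

    @property
    def host_mask(self) -> np.ndarray:
        return ~self.viral_mask

    def subset_cells(self, barcodes: Iterable[str]) -> "ExpressionMatrix":
        idx = self.cells.index.get_indexer(pd.Index(barcodes))
        if (idx < 0).any():
            raise ValidationError("unknown barcode in subset request")
        return ExpressionMatrix(
            self.counts[idx], self.genes, self.cells.iloc[idx].copy()
        )

    def total_counts(self) -> np.ndarray:
        """Per-cell total counts (host + viral)."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (cells x genes)."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(), obs=self.cells.copy(), var=self.genes.copy()
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nv = int(self.viral_mask.sum())
        return (
            f"ExpressionMatrix({self.n_cells} cells x {self.n_genes} genes, "
            f"{nv} viral)"
        )


@dataclass
class MarkerDB:
    """Per-cell-type positive/negative marker symbol sets (uppercased)."""

    positive: dict[str, frozenset[str]]
    negative: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positive = {t: frozenset(s.upper() for s in m) for t, m in self.positive.items()}
        self.negative = {t: frozenset(s.upper() for s in m) for t, m in self.negative.items()}
        for t, pos in self.positive.items():
            overlap = pos & self.negative.get(t, frozenset())
            if overlap:
                raise ValidationError(
                    f"markers {sorted(overlap)} are both positive and negative "
                    f"for type {t!r}"
                )

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.positive) | set(self.negative))

    def all_symbols(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.positive.values():
            out |= s
        for s in self.negative.values():
            out |= s
        return frozenset(out)


@dataclass(frozen=True)
class CnvCall:
    """Arm-level expression-dosage call for one target group."""

    target_group: str
    arm: str
    direction: str  # "gain" | "loss"
    score: float  # mean smoothed log2 ratio over the arm
    n_genes: int


@dataclass
class SignatureSet:
    """Host-gene signature: genes most correlated with group viral load."""

    positive: list[str]  # R descending
    negative: list[str]  # R ascending
    r_threshold: float = 0.5
    top_n: int = 300


def genes_frame(records: Iterable[GeneRecord]) -> pd.DataFrame:
    """Build the gene sidecar table from :class:`GeneRecord` objects."""
    rows = [
        {
            "gene_id": g.gene_id,
            "symbol": g.symbol,
            "origin": g.origin,
            "chromosome": g.chromosome,
            "arm": g.arm,
            "start": g.start,
            "functional_class": g.functional_class,
            "temporal_class": g.temporal_class,
        }
        for g in records
    ]
    df = pd.DataFrame(rows, columns=["gene_id"] + GENE_COLUMNS)
    return df.set_index("gene_id")


def cells_frame(records: Iterable[CellRecord]) -> pd.DataFrame:
    """Build the cell sidecar table from :class:`CellRecord` objects."""
    rows = [
        {
            "barcode": c.barcode,
            "sample": c.sample,
            "status": c.status,
            "assigned_type": c.assigned_type,
            "cluster": c.cluster,
        }
        for c in records
    ]
    df = pd.DataFrame(rows, columns=["barcode"] + CELL_COLUMNS)
    return df.set_index("barcode")
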