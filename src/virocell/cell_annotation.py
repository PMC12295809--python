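"""Marker-based cell-type annotation with specificity-weighted scoring.

In the spirit of marker-database annotators (ScType-like, not a
reproduction): each marker is weighted by the inverse of the number of
cell types claiming it, expression is normalized per cell and z-scored
per gene across cells, and a cell's score for a type is the weighted sum
of its positive-marker z-scores minus the weighted sum of its
negative-marker z-scores. Cells whose best score is not positive are
left "unclassified"; the same rule at cluster level requires the summed
score to reach a quarter of the cluster size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from virocell.datatypes import ExpressionMatrix, MarkerDB
from virocell.errors import ConfigurationError
from virocell.normalize import cp10k_log1p

log = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


@dataclass
class AnnotationResult:
    """Per-cell type scores and assignments."""

    scores: pd.DataFrame  # cells x types
    assigned: pd.Series  # barcode -> type or "unclassified"
    n_ties: int = 0
    missing_symbols: list[str] = field(default_factory=list)


def specificity_weights(db: MarkerDB) -> dict[str, float]:
    """weight(marker) = 1 / (number of types whose positive set holds it)."""
    counts: dict[str, int] = {}
    for members in db.positive.values():
        for m in members:
            counts[m] = counts.get(m, 0) + 1
    weights = {m: 1.0 / k for m, k in counts.items()}
    # negative-only markers default to weight 1
    for members in db.negative.values():
        for m in members:
            weights.setdefault(m, 1.0)
    return weights


def score_cells(matrix: ExpressionMatrix, db: MarkerDB) -> AnnotationResult:
    """Score every cell against every type and assign by argmax."""
    if matrix.n_cells < 2:
        raise ConfigurationError("scoring needs >= 2 cells for cross-cell z-scores")
    symbols = matrix.genes["symbol"].astype(str).str.upper()
    sym_to_col: dict[str, int] = {}
    for col, s in enumerate(symbols):
        sym_to_col.setdefault(s, col)

    wanted = db.all_symbols()
    present = sorted(wanted & set(sym_to_col))
    missing = sorted(wanted - set(sym_to_col))
    if not present:
        raise ConfigurationError(
            f"no marker symbol overlaps the gene universe; missing: {missing}"
        )
    if missing:
        log.warning("markers absent from gene universe: %s", missing)

    values, gene_idx = cp10k_log1p(matrix, genes="all", denominator="total")
    cols = np.array([sym_to_col[s] for s in present])
    x = np.asarray(values[:, cols].todense())
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    z = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    zcol = {s: z[:, i] for i, s in enumerate(present)}

    weights = specificity_weights(db)
    types = db.cell_types
    scores = np.zeros((matrix.n_cells, len(types)))
    for j, t in enumerate(types):
        for m in db.positive.get(t, ()):  # type: ignore[arg-type]
            if m in zcol:
                scores[:, j] += weights[m] * zcol[m]
        for m in db.negative.get(t, ()):  # type: ignore[arg-type]
            if m in zcol:
                scores[:, j] -= weights[m] * zcol[m]

    score_df = pd.DataFrame(scores, index=matrix.barcodes, columns=types)
    best = score_df.max(axis=1)
    # ties broken by lexicographic type name (idxmax takes the first column,
    # and `types` is sorted)
    n_ties = int(((score_df.eq(best, axis=0)).sum(axis=1) > 1).sum())
    if n_ties:
        log.info("%d cells had tied best scores; lexicographic tie-break", n_ties)
    assigned = score_df.idxmax(axis=1).where(best > 0, UNCLASSIFIED)
    assigned.name = "assigned_type"
    return AnnotationResult(
        scores=score_df, assigned=assigned, n_ties=n_ties, missing_symbols=missing
    )


def annotate_clusters(result: AnnotationResult, clusters: pd.Series) -> pd.Series:
    """Aggregate cell scores per cluster; label by argmax with an n/4 floor."""
    clusters = clusters.reindex(result.scores.index)
    if clusters.isna().any():
        raise ConfigurationError("cluster ids must cover all cells")
    labels = {}
    for cid, idx in result.scores.groupby(clusters).groups.items():
        total = result.scores.loc[idx].sum(axis=0)
        best = total.max()
        labels[cid] = (
            total.idxmax() if best >= len(idx) / 4.0 else UNCLASSIFIED
        )
    return pd.Series(labels, name="cluster_label")
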