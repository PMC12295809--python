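"""Viral transcripts vs total viral load, and temporal-class tallies.

Individual viral genes are correlated (Pearson R) against the group mean
viral transcript fraction across infected cell-type groups, using
whole-transcriptome counts-per-10k levels — a viral transcript is treated
like any other transcript, not as a share of viral counts. Poxvirus
genes carry temporal expression classes (early genes: replication
machinery; late genes: structural proteins); the tally operations count
classes among correlated genes. A packaged reference table of 20
virus-encoded transcripts with published correlation coefficients and
temporal classes serves as a worked example and integrity-checked
fixture.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from virocell.datatypes import TEMPORAL_CLASSES, ExpressionMatrix
from virocell.errors import ValidationError
from virocell.correlation_signatures import pearson_by_row
from virocell.normalize import cp10k_log1p

log = logging.getLogger(__name__)

_FIXTURE_ROWS = 20
_FIXTURE_R_SUM = 12.06  # integrity checksum: sum of the packaged coefficients


@dataclass
class TemporalTally:
    """Counts of viral temporal classes among a set of gene records."""

    early: int
    late: int
    early_late: int
    unknown: int

    @property
    def n_known(self) -> int:
        return self.early + self.late + self.early_late

    @property
    def total(self) -> int:
        return self.n_known + self.unknown


def viral_gene_group_means(
    matrix: ExpressionMatrix, groups: pd.Series, min_cells: int = 20
) -> pd.DataFrame:
    """Mean log1p(CP10K, total denominator) per viral gene per group."""
    groups = groups.dropna()
    values, gene_idx = cp10k_log1p(matrix, genes="viral", denominator="total")
    gene_ids = matrix.gene_ids[gene_idx]
    out = {}
    for label, members in groups.groupby(groups).groups.items():
        idx = matrix.cells.index.get_indexer(pd.Index(members))
        idx = idx[idx >= 0]
        if len(idx) < min_cells:
            log.warning("group %s has %d cells (< %d); excluded", label, len(idx), min_cells)
            continue
        out[label] = np.asarray(values[idx].mean(axis=0)).ravel()
    if not out:
        raise ValidationError("no group meets the minimum cell count")
    return pd.DataFrame(out, index=gene_ids)


def correlate_viral_genes(
    matrix: ExpressionMatrix,
    groups: pd.Series,
    group_viral_means: pd.Series,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Per-viral-gene Pearson R against the groups' mean viral fraction.

    Returns a frame indexed by viral gene id with columns
    ``gene, R, temporal_class, annotation``; genes constant across groups
    are excluded.
    """
    if not matrix.viral_mask.any():
        raise ValidationError("no viral genes in the gene annotation")
    means = viral_gene_group_means(matrix, groups, min_cells=min_cells)
    means = means[group_viral_means.index.intersection(means.columns)]
    r, excluded = pearson_by_row(means, group_viral_means[means.columns])
    if excluded:
        log.info("%d constant viral genes excluded", len(excluded))
    genes = matrix.genes.loc[r.index]
    return pd.DataFrame(
        {
            "gene": genes["symbol"],
            "R": r,
            "temporal_class": genes["temporal_class"],
            "annotation": genes["functional_class"].fillna(""),
        }
    )


def check_no_negative(
    records: pd.DataFrame, r_threshold: float = 0.5
) -> tuple[bool, pd.DataFrame]:
    """True iff no viral gene correlates below -``r_threshold``."""
    offending = records[records["R"] < -r_threshold]
    return offending.empty, offending


def tally_temporal_classes(records: pd.DataFrame) -> TemporalTally:
    """Count Early / Late / EarlyLate / Unknown classes in the records."""
    classes = records["temporal_class"].fillna("Unknown")
    bad = set(classes) - set(TEMPORAL_CLASSES)
    if bad:
        raise ValidationError(f"unknown temporal classes: {sorted(bad)}")
    counts = classes.value_counts()
    return TemporalTally(
        early=int(counts.get("Early", 0)),
        late=int(counts.get("Late", 0)),
        early_late=int(counts.get("EarlyLate", 0)),
        unknown=int(counts.get("Unknown", 0)),
    )


def load_table_fixture() -> pd.DataFrame:
    """Load the packaged viral-gene correlation table (20 records).

    The table lists virus-encoded transcripts positively correlated with
    mean viral load in cultured human brain cells, with their published
    Pearson coefficients and temporal classes. An integrity check guards
    against accidental edits.
    """
    ref = importlib.resources.files("virocell").joinpath(
        "data/viral_gene_correlations.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    df = df.rename(columns={"r": "R"})
    df["annotation"] = df["annotation"].fillna("")
    if len(df) != _FIXTURE_ROWS or round(float(df["R"].sum()), 2) != _FIXTURE_R_SUM:
        raise ValidationError(
            "viral gene fixture corrupted: expected "
            f"{_FIXTURE_ROWS} rows with coefficient sum {_FIXTURE_R_SUM}"
        )
    return df.set_index("gene", drop=False)
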