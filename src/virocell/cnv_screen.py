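"""Arm-level expression-dosage CNV screen from pseudobulk log-ratios.

Single-cell counts of a target cell group and a reference group (by
default, cells from non-malignant cultures) are summed into pseudobulk
profiles, scaled to counts-per-million, and compared gene-by-gene as a
log2 ratio centred on the genome-wide median. A running median along
each chromosome arm suppresses single-gene outliers; an arm whose mean
smoothed ratio clears +/- ``threshold`` (log2 scale) is called a gain or
a loss. This is a deliberately simple dosage screen, not a per-cell CNV
caller: it answers whether a cell group carries arm-scale events
relative to the reference.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

from virocell.datatypes import CnvCall, ExpressionMatrix
from virocell.errors import ValidationError

log = logging.getLogger(__name__)

MIN_GROUP_CELLS = 20
MIN_ARM_GENES = 10


def pseudobulk_log_ratio(
    matrix: ExpressionMatrix,
    target_cells: Sequence[str],
    reference_cells: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Median-centred per-host-gene log2 CPM ratio, target vs reference."""
    for name, cells in (("target", target_cells), ("reference", reference_cells)):
        if len(cells) < MIN_GROUP_CELLS:
            raise ValidationError(
                f"{name} group has {len(cells)} cells; need >= {MIN_GROUP_CELLS}"
            )

    host = matrix.host_mask

    def cpm(cells: Sequence[str]) -> np.ndarray:
        idx = matrix.cells.index.get_indexer(pd.Index(cells))
        if (idx < 0).any():
            raise ValidationError("unknown barcode in CNV group")
        bulk = np.asarray(matrix.counts[idx][:, host].sum(axis=0)).ravel().astype(float)
        return bulk / bulk.sum() * 1e6

    ratio = np.log2((cpm(target_cells) + pseudocount) / (cpm(reference_cells) + pseudocount))
    ratio = ratio - np.median(ratio)
    return pd.Series(ratio, index=matrix.gene_ids[host], name="log2_ratio")


def _running_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centred running median, window truncated at the edges."""
    s = pd.Series(values)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def smooth_and_call(
    ratios: pd.Series,
    genes: pd.DataFrame,
    window: int = 51,
    threshold: float = 0.3,
    target_group: str = "target",
) -> list[CnvCall]:
    """Call arm gains/losses from smoothed log2 ratios.

    ``genes`` must carry ``arm`` and ``start`` columns indexed by gene id.
    """
    if window % 2 == 0:
        raise ValidationError(f"window must be odd, got {window}")
    genes = genes.loc[ratios.index]
    calls: list[CnvCall] = []
    for arm, sub in genes.groupby("arm", sort=True):
        if len(sub) < MIN_ARM_GENES:
            log.warning("arm %s has %d genes (< %d); skipped", arm, len(sub), MIN_ARM_GENES)
            continue
        ordered = sub.sort_values(["start"]).index
        smoothed = _running_median(ratios.loc[ordered].to_numpy(), window)
        score = float(smoothed.mean())
        if score >= threshold:
            calls.append(CnvCall(target_group, str(arm), "gain", score, len(sub)))
        elif score <= -threshold:
            calls.append(CnvCall(target_group, str(arm), "loss", score, len(sub)))
    return calls


def screen(
    matrix: ExpressionMatrix,
    target_cells: Sequence[str],
    reference_cells: Sequence[str],
    window: int = 51,
    threshold: float = 0.3,
    pseudocount: float = 1.0,
    target_group: str = "target",
) -> tuple[list[CnvCall], pd.Series]:
    """Full screen: pseudobulk ratio then arm calls. Returns (calls, ratios)."""
    ratios = pseudobulk_log_ratio(matrix, target_cells, reference_cells, pseudocount)
    host_genes = matrix.genes.loc[ratios.index]
    calls = smooth_and_call(ratios, host_genes, window, threshold, target_group)
    return calls, ratios
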