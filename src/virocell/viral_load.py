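"""Per-cell viral transcript fraction and cell-type susceptibility ranking.

The viral transcript fraction — the share of a cell's transcript counts
mapping to viral genes — is the per-cell viral-load statistic. Groups are
cell-type x infection-status; infected groups are ranked by mean fraction
and compared pairwise with Welch t-tests under a Holm-Bonferroni
family-wise correction. The rendered ordering string joins adjacent
groups with ``>``, upgraded to ``>>`` where the adjacent pair is
significant at the chosen alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from virocell.datatypes import ExpressionMatrix
from virocell.errors import ConfigurationError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class ViralLoadProfile:
    """Per-cell viral fractions plus per-(type x status) group summaries."""

    per_cell: pd.DataFrame  # index barcode; fraction, cell_type, status
    groups: pd.DataFrame  # index (cell_type, status); n_cells, mean, median, low_confidence
    n_dropped_cells: int = 0


@dataclass
class SusceptibilityRanking:
    """Infected groups ordered by mean viral fraction with pairwise tests."""

    order: list[str]  # descending mean fraction
    raw_p: pd.DataFrame
    adjusted_p: pd.DataFrame
    significant: pd.DataFrame  # adjusted_p < alpha
    alpha: float
    ordering_string: str
    warnings: list[str] = field(default_factory=list)


def viral_fraction(matrix: ExpressionMatrix) -> tuple[pd.Series, int]:
    """Per-cell viral transcript fraction.

    Cells with zero total counts are dropped; the dropped count is
    returned alongside (and logged).
    """
    if not matrix.viral_mask.any():
        raise ConfigurationError("no viral genes in the gene annotation")
    totals = matrix.total_counts().astype(float)
    viral = np.asarray(matrix.counts[:, matrix.viral_mask].sum(axis=1)).ravel()
    keep = totals > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropped %d cells with zero total counts", n_dropped)
    frac = pd.Series(
        viral[keep] / totals[keep], index=matrix.barcodes[keep], name="viral_fraction"
    )
    return frac, n_dropped


def summarize_groups(
    fractions: pd.Series,
    cells: pd.DataFrame,
    min_group_size: int = 20,
    cell_types: pd.Series | None = None,
) -> ViralLoadProfile:
    """Summarize viral fractions per (cell type x infection status) group.

    ``cell_types`` overrides ``cells["assigned_type"]``; cells without a
    type are grouped as "other".
    """
    cells = cells.loc[fractions.index]
    if cell_types is None:
        types = cells["assigned_type"]
    else:
        types = cell_types.reindex(fractions.index)
    types = types.fillna("other").astype(str).replace({"None": "other"})
    per_cell = pd.DataFrame(
        {
            "viral_fraction": fractions,
            "cell_type": types,
            "status": cells["status"].astype(str),
        }
    )
    if per_cell.empty:
        raise ValidationError("no cells to summarize")
    grouped = per_cell.groupby(["cell_type", "status"])["viral_fraction"]
    groups = grouped.agg(n_cells="size", mean_fraction="mean", median_fraction="median")
    groups["low_confidence"] = groups["n_cells"] < min_group_size
    return ViralLoadProfile(per_cell=per_cell, groups=groups)


def holm_bonferroni(pvals) -> np.ndarray:
    """Step-down Holm-Bonferroni adjustment, returned in input order.

    adj_(i) = max_{j<=i} min(1, (m-j+1) * p_(j)) over the ascending sort.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = np.minimum(1.0, (m - np.arange(m)) * p[order])
    stepped = np.maximum.accumulate(scaled)
    adj = np.empty(m)
    adj[order] = stepped
    return adj


def rank_susceptibility(
    profile: ViralLoadProfile, alpha: float = 0.01
) -> SusceptibilityRanking:
    """Rank infected groups by mean viral fraction with pairwise Welch tests."""
    warnings: list[str] = []
    per_cell = profile.per_cell[profile.per_cell["status"] == "infected"]
    sizes = per_cell.groupby("cell_type").size()
    groups = sizes[sizes >= 2].index.tolist()
    if len(groups) < 2:
        raise ValidationError(
            f"need >= 2 infected groups with n >= 2, got {len(groups)}"
        )
    means = per_cell.groupby("cell_type")["viral_fraction"].mean()
    order = sorted(groups, key=lambda g: (-means[g], g))

    values = {g: per_cell.loc[per_cell["cell_type"] == g, "viral_fraction"].to_numpy() for g in groups}
    pairs = [(a, b) for i, a in enumerate(order) for b in order[i + 1 :]]
    raw = []
    for a, b in pairs:
        x, y = values[a], values[b]
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            # Welch statistic undefined without any variance
            warnings.append(f"degenerate zero-variance pair ({a}, {b}): p set to 1")
            raw.append(1.0)
            continue
        p = stats.ttest_ind(x, y, equal_var=False).pvalue
        if np.isnan(p):
            warnings.append(f"degenerate pair ({a}, {b}): p set to 1")
            p = 1.0
        raw.append(float(p))
    adj = holm_bonferroni(raw)

    raw_m = pd.DataFrame(np.ones((len(order), len(order))), index=order, columns=order)
    adj_m = raw_m.copy()
    for (a, b), pr, pa in zip(pairs, raw, adj):
        raw_m.loc[a, b] = raw_m.loc[b, a] = pr
        adj_m.loc[a, b] = adj_m.loc[b, a] = pa
    sig = adj_m < alpha

    parts = [order[0]]
    for a, b in zip(order, order[1:]):
        parts.append(" >> " if sig.loc[a, b] else " > ")
        parts.append(b)
    return SusceptibilityRanking(
        order=order,
        raw_p=raw_m,
        adjusted_p=adj_m,
        significant=sig,
        alpha=alpha,
        ordering_string="".join(parts),
        warnings=warnings,
    )
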