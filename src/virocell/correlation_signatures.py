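"""Host-gene correlates of viral load across cell-type groups.

The central inference: aggregate normalized host expression into group
means (one value per gene per infected cell-type group), correlate each
gene's profile with the groups' mean viral transcript fraction (Pearson
R), and select signature genes beyond an |R| threshold. The matched
pre-infection variant correlates *control* group means of each cell type
against the viral means of the corresponding infected groups, asking
which baseline transcripts predict later susceptibility. A per-type
Wilcoxon differential-expression test (infected vs control, BH-adjusted)
supplies the infection-response gene lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from virocell.datatypes import ExpressionMatrix, SignatureSet
from virocell.errors import ValidationError
from virocell.normalize import cp10k_log1p

log = logging.getLogger(__name__)

MIN_GROUP_CELLS = 20


@dataclass
class DifferentialExpressionResult:
    """Per-(gene, type) infected-vs-control statistics + common-gene table."""

    per_type: dict[str, pd.DataFrame]  # type -> gene table (log2_fc, p, q)
    common_upregulated: pd.DataFrame  # top genes by number of types upregulated
    skipped_types: list[str] = field(default_factory=list)


def group_mean_expression(
    matrix: ExpressionMatrix,
    groups: pd.Series,
    min_cells: int = MIN_GROUP_CELLS,
    genes: str = "host",
    denominator: str = "host",
) -> pd.DataFrame:
    """Mean log1p(CP10K) per gene per group (genes x groups).

    ``groups`` maps barcodes to group labels; cells absent from it are
    ignored; groups below ``min_cells`` are dropped with a warning.
    """
    groups = groups.dropna()
    values, gene_idx = cp10k_log1p(matrix, genes=genes, denominator=denominator)
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


def pearson_by_row(means: pd.DataFrame, y: pd.Series) -> tuple[pd.Series, list[str]]:
    """Pearson R of every row of ``means`` against ``y`` (shared columns).

    Rows with zero variance are excluded; their ids are returned.
    """
    if not set(means.columns) == set(y.index):
        raise ValidationError(
            f"group labels differ: {sorted(means.columns)} vs {sorted(y.index)}"
        )
    if len(y) < 3:
        raise ValidationError(f"need >= 3 groups, got {len(y)}")
    x = means[y.index].to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    if np.std(yv) == 0:
        raise ValidationError("viral means are constant across groups")
    xc = x - x.mean(axis=1, keepdims=True)
    yc = yv - yv.mean()
    xs = np.sqrt((xc**2).sum(axis=1))
    keep = xs > 0
    r = np.full(x.shape[0], np.nan)
    r[keep] = (xc[keep] @ yc) / (xs[keep] * np.sqrt((yc**2).sum()))
    excluded = list(means.index[~keep])
    return pd.Series(r[keep], index=means.index[keep], name="R"), excluded


def correlate_with_viral_load(
    gene_group_means: pd.DataFrame,
    group_viral_means: pd.Series,
    mode: str = "post_infection",
) -> pd.DataFrame:
    """Per-gene Pearson R against group mean viral fraction.

    Returns a frame with columns ``R, n_groups, mode``; zero-variance
    genes are excluded (logged).
    """
    r, excluded = pearson_by_row(gene_group_means, group_viral_means)
    if excluded:
        log.info("%d constant genes excluded from correlation", len(excluded))
    return pd.DataFrame(
        {"R": r, "n_groups": len(group_viral_means), "mode": mode}
    )


def select_signatures(
    records: pd.DataFrame, r_threshold: float = 0.5, top_n: int = 300
) -> SignatureSet:
    """Top positively/negatively correlated genes beyond the R threshold."""
    if "R" not in records.columns:
        raise ValidationError("records need an R column")
    r = records["R"]
    # ties on R broken by gene id: stable sort by R after an index sort
    pos = (
        records[r > r_threshold]
        .sort_index(kind="stable")
        .sort_values(["R"], ascending=False, kind="stable")
        .index[:top_n]
    )
    neg = (
        records[r < -r_threshold]
        .sort_index(kind="stable")
        .sort_values(["R"], ascending=True, kind="stable")
        .index[:top_n]
    )
    return SignatureSet(
        positive=list(pos), negative=list(neg), r_threshold=r_threshold, top_n=top_n
    )


def pre_infection_correlation(
    control_group_means: pd.DataFrame,
    infected_group_viral_means: pd.Series,
    type_matching: dict[str, str],
) -> pd.DataFrame:
    """Correlate baseline (control) expression with matched infected viral load.

    ``type_matching`` maps each control group label (a column of
    ``control_group_means``) to the infected group label whose viral mean
    it should be paired with.
    """
    missing = [g for g in control_group_means.columns if g not in type_matching]
    if missing:
        log.warning("control groups without a matched infected group: %s", missing)
    pairs = {
        ctl: inf
        for ctl, inf in type_matching.items()
        if ctl in control_group_means.columns and inf in infected_group_viral_means.index
    }
    if len(pairs) < 3:
        raise ValidationError(f"need >= 3 matched control/infected pairs, got {len(pairs)}")
    ctl_cols = list(pairs)
    y = pd.Series(
        [infected_group_viral_means[pairs[c]] for c in ctl_cols], index=ctl_cols
    )
    return correlate_with_viral_load(
        control_group_means[ctl_cols], y, mode="pre_infection"
    )


def shared_signature_genes(
    pre: SignatureSet, post: SignatureSet
) -> tuple[list[str], list[str]]:
    """Genes in both the pre- and post-infection signatures (post order)."""
    pre_pos, pre_neg = set(pre.positive), set(pre.negative)
    shared_pos = [g for g in post.positive if g in pre_pos]
    shared_neg = [g for g in post.negative if g in pre_neg]
    return shared_pos, shared_neg


def differential_expression(
    matrix: ExpressionMatrix,
    cell_types: pd.Series,
    min_cells: int = MIN_GROUP_CELLS,
    q_threshold: float = 0.05,
    top_n_common: int = 50,
) -> DifferentialExpressionResult:
    """Per-type infected-vs-control Wilcoxon rank-sum DE on host genes.

    log2 fold changes come from group means on the transformed scale with
    a small pseudocount; q-values are Benjamini-Hochberg within type.
    The "commonly upregulated" table ranks genes by the number of types
    in which they are significantly up (q < ``q_threshold``, log2FC > 0).
    """
    eps = 1e-9
    values, gene_idx = cp10k_log1p(matrix, genes="host", denominator="host")
    gene_ids = matrix.gene_ids[gene_idx]
    types = cell_types.reindex(matrix.barcodes)
    status = matrix.cells["status"]

    per_type: dict[str, pd.DataFrame] = {}
    skipped: list[str] = []
    for t in sorted(types.dropna().unique()):
        inf_idx = np.flatnonzero((types == t) & (status == "infected"))
        ctl_idx = np.flatnonzero((types == t) & (status == "control"))
        if len(inf_idx) < min_cells or len(ctl_idx) < min_cells:
            skipped.append(t)
            log.warning(
                "type %s skipped for DE (infected=%d, control=%d)",
                t, len(inf_idx), len(ctl_idx),
            )
            continue
        x = np.asarray(values[inf_idx].todense())
        y = np.asarray(values[ctl_idx].todense())
        res = stats.mannwhitneyu(x, y, axis=0, alternative="two-sided", method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
        # genes identical in both arms: test undefined, call them null
        p = np.where(np.isnan(p), 1.0, p)
        q = multipletests(p, method="fdr_bh")[1]
        lfc = np.log2((x.mean(axis=0) + eps) / (y.mean(axis=0) + eps))
        per_type[t] = pd.DataFrame(
            {"log2_fc": lfc, "p": p, "q": q}, index=gene_ids
        )
    if not per_type:
        raise ValidationError("no cell type has both infected and control arms")

    up_counts = pd.Series(0, index=gene_ids, dtype=int)
    mean_lfc = pd.Series(0.0, index=gene_ids)
    for t, df in per_type.items():
        up = (df["q"] < q_threshold) & (df["log2_fc"] > 0)
        up_counts[up[up].index] += 1
        mean_lfc += df["log2_fc"]
    mean_lfc /= len(per_type)
    common = pd.DataFrame(
        {"n_types_up": up_counts, "mean_log2_fc": mean_lfc}
    )
    common = common[common["n_types_up"] > 0]
    common = common.sort_index(kind="stable").sort_values(
        ["n_types_up", "mean_log2_fc"], ascending=[False, False], kind="stable"
    )
    return DifferentialExpressionResult(
        per_type=per_type,
        common_upregulated=common.head(top_n_common),
        skipped_types=skipped,
    )
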