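#!/usr/bin/env python
"""Host-gene correlates of viral load, before and after infection.

Correlates each host gene's infected group-mean expression with the
groups' mean viral fraction (post-infection signature), repeats the
computation on the matched control groups (pre-infection signature),
intersects the two, and runs per-type infected-vs-control differential
expression to find commonly upregulated genes.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import outdir, study_dataset

from virocell import correlation_signatures as cs
from virocell.viral_load import summarize_groups, viral_fraction


def main() -> None:
    matrix, truth = study_dataset()
    frac, _ = viral_fraction(matrix)
    profile = summarize_groups(frac, matrix.cells, cell_types=truth.cell_types)
    viral_means = profile.groups.xs("infected", level="status")["mean_fraction"]

    infected = (matrix.cells["status"] == "infected").to_numpy()
    post_means = cs.group_mean_expression(matrix, truth.cell_types[infected])
    viral_means = viral_means[viral_means.index.intersection(post_means.columns)]
    post = cs.correlate_with_viral_load(post_means[viral_means.index], viral_means)
    post_sig = cs.select_signatures(post)
    post.round(4).to_csv(outdir() / "05_correlations_post.tsv", sep="\t")

    ctl_means = cs.group_mean_expression(matrix, truth.cell_types[~infected])
    pre = cs.pre_infection_correlation(
        ctl_means, viral_means, {t: t for t in ctl_means.columns}
    )
    pre_sig = cs.select_signatures(pre)
    pre.round(4).to_csv(outdir() / "05_correlations_pre.tsv", sep="\t")

    shared_pos, shared_neg = cs.shared_signature_genes(pre_sig, post_sig)
    pd.Series(shared_pos, name="gene_id").to_csv(
        outdir() / "05_shared_positive.tsv", sep="\t", index=False
    )

    print(f"correlated {len(post)} host genes across {len(viral_means)} infected groups")
    print(f"post-infection signature: {len(post_sig.positive)} positive / "
          f"{len(post_sig.negative)} negative genes beyond |R| > 0.5")
    print(f"pre-infection signature:  {len(pre_sig.positive)} positive / "
          f"{len(pre_sig.negative)} negative")
    print(f"shared (pre AND post): {len(shared_pos)} positive, {len(shared_neg)} negative")
    pos_hit = len(set(truth.planted_pos) & set(post_sig.positive))
    neg_hit = len(set(truth.planted_neg) & set(post_sig.negative))
    print(f"planted coupling recovered post-infection: "
          f"{pos_hit}/{len(truth.planted_pos)} positive, "
          f"{neg_hit}/{len(truth.planted_neg)} negative")

    de = cs.differential_expression(matrix, truth.cell_types)
    de.common_upregulated.round(3).to_csv(
        outdir() / "05_de_common_upregulated.tsv", sep="\t"
    )
    top = set(de.common_upregulated.index[:50])
    print(f"\nDE tested types: {sorted(de.per_type)}; "
          f"infection-induced genes in top-50 common list: "
          f"{len(set(truth.induced_genes) & top)}/{len(truth.induced_genes)}")


if __name__ == "__main__":
    main()
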