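#!/usr/bin/env python
"""Viral transcripts vs total viral load and their temporal classes.

Correlates each viral gene's group-mean level with the groups' mean
viral fraction, verifies that no viral transcript anti-correlates with
total viral RNA, and tallies poxvirus temporal classes — alongside the
same tallies on the packaged reference table of 20 virus-encoded
transcripts.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import outdir, study_dataset

from virocell import viral_gene_analysis as vga
from virocell.viral_load import summarize_groups, viral_fraction


def show(label, tally):
    print(f"{label}: Early={tally.early} Late={tally.late} "
          f"Early/Late={tally.early_late} Unknown={tally.unknown} "
          f"(known-stage total {tally.n_known})")


def main() -> None:
    matrix, truth = study_dataset()
    frac, _ = viral_fraction(matrix)
    profile = summarize_groups(frac, matrix.cells, cell_types=truth.cell_types)
    viral_means = profile.groups.xs("infected", level="status")["mean_fraction"]

    records = vga.correlate_viral_genes(matrix, truth.cell_types, viral_means)
    records.round(4).to_csv(outdir() / "06_viral_gene_correlations.tsv", sep="\t")

    ok, offending = vga.check_no_negative(records)
    print(f"correlated {len(records)} viral genes with group mean viral load")
    print("no viral transcript anti-correlates (R < -0.5):", ok)
    if not ok:
        print("offending:", list(offending["gene"]))
    show("correlated (R > 0.5) synthetic viral genes",
         vga.tally_temporal_classes(records[records["R"] > 0.5]))

    table = vga.load_table_fixture()
    show("packaged reference table", vga.tally_temporal_classes(table))
    print(f"reference table extremes: max R = {table['R'].max():.2f} "
          f"({table.loc[table['R'].idxmax(), 'gene']}), "
          f"min R = {table['R'].min():.2f}")


if __name__ == "__main__":
    main()
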