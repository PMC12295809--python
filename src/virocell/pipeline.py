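"""End-to-end orchestration of the infection analysis.

Fixed stage order: load/generate -> annotate -> viral load -> suscepti-
bility ranking -> CNV screen -> correlation signatures (post, pre,
shared) -> differential expression -> viral-gene analysis. Every stage
either contributes to the report or records an explicit skip reason.
All randomness flows from the single configured seed; the JSON report is
byte-stable across reruns except for the isolated ``timestamp`` field.
"""

from __future__ import annotations

import json
import logging
import time
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd

from virocell import cell_annotation, cnv_screen, correlation_signatures as cs
from virocell import viral_gene_analysis as vga
from virocell import viral_load as vl
from virocell.config import SyntheticConfig
from virocell.datatypes import ExpressionMatrix, MarkerDB
from virocell.errors import ConfigurationError
from virocell.io_formats import read_dataset, read_marker_db, write_dataset
from virocell.synthetic import GroundTruth, generate_dataset

log = logging.getLogger(__name__)

PIPELINE_DEFAULTS = {
    "alpha": 0.01,
    "min_group": 20,
    "r_threshold": 0.5,
    "top_n": 300,
}


def _load_inputs(
    config: dict[str, Any],
) -> tuple[ExpressionMatrix, GroundTruth | None, MarkerDB | None]:
    if ("dataset" in config) == ("synthetic" in config):
        raise ConfigurationError(
            "config must name either a dataset directory or a synthetic block"
        )
    truth = None
    if "dataset" in config:
        matrix = read_dataset(config["dataset"])
    else:
        synth = dict(config["synthetic"])
        if "seed" in config:
            synth["seed"] = int(config["seed"])
        scfg = SyntheticConfig.from_dict(synth)
        matrix, truth = generate_dataset(scfg)
    markers = None
    if config.get("markers"):
        markers = read_marker_db(config["markers"])
    elif truth is not None:
        markers = truth.marker_db()
    return matrix, truth, markers


def run_pipeline(
    config: dict[str, Any], out_dir: str | Path | None = None
) -> dict[str, Any]:
    """Run every stage and return (and optionally write) the run report."""
    cfg = {**PIPELINE_DEFAULTS, **config}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {
        "config": {k: v for k, v in cfg.items()},
        "stages": {},
        "warnings": [],
    }
    timings: dict[str, float] = {}

    def stage(name: str):
        log.info("stage %s: start", name)
        timings[name] = time.perf_counter()
        return name

    def done(name: str) -> None:
        timings[name] = round(time.perf_counter() - timings[name], 3)
        log.info("stage %s: done in %.2fs", name, timings[name])

    # -- load ----------------------------------------------------------
    s = stage("load")
    matrix, truth, markers = _load_inputs(cfg)
    report["stages"]["load"] = {
        "n_cells": matrix.n_cells,
        "n_genes": matrix.n_genes,
        "n_viral_genes": int(matrix.viral_mask.sum()),
        "synthetic": truth is not None,
    }
    if out is not None and truth is not None:
        write_dataset(matrix, out / "dataset")
    done(s)

    # -- annotation ----------------------------------------------------
    s = stage("annotation")
    if markers is None:
        have = matrix.cells["assigned_type"].notna()
        if not have.all():
            raise ConfigurationError(
                "no marker database and cells.tsv lacks assigned types"
            )
        cell_types = matrix.cells["assigned_type"].astype(str)
        report["stages"]["annotation"] = {
            "skipped": "using assigned_type column from the dataset"
        }
    else:
        ann = cell_annotation.score_cells(matrix, markers)
        cell_types = ann.assigned
        info = {
            "n_unclassified": int((ann.assigned == cell_annotation.UNCLASSIFIED).sum()),
            "n_ties": ann.n_ties,
        }
        if truth is not None:
            agree = (ann.assigned == truth.cell_types.reindex(ann.assigned.index)).mean()
            info["accuracy_vs_ground_truth"] = round(float(agree), 4)
        report["stages"]["annotation"] = info
        if out is not None:
            ann.assigned.to_csv(out / "cell_types.tsv", sep="\t")
    done(s)

    # -- viral load + ranking ------------------------------------------
    s = stage("viral_load")
    fractions, n_dropped = vl.viral_fraction(matrix)
    profile = vl.summarize_groups(
        fractions, matrix.cells, min_group_size=cfg["min_group"], cell_types=cell_types
    )
    profile.n_dropped_cells = n_dropped
    report["stages"]["viral_load"] = {
        "n_dropped_zero_total": n_dropped,
        "groups": {
            f"{t}|{st}": {
                "n": int(row["n_cells"]),
                "mean": round(float(row["mean_fraction"]), 6),
                "median": round(float(row["median_fraction"]), 6),
                "low_confidence": bool(row["low_confidence"]),
            }
            for (t, st), row in profile.groups.iterrows()
        },
    }
    if out is not None:
        profile.per_cell.to_csv(out / "viral_fractions.tsv", sep="\t")
        profile.groups.to_csv(out / "viral_load_groups.tsv", sep="\t")
    done(s)

    s = stage("ranking")
    ranking = vl.rank_susceptibility(profile, alpha=cfg["alpha"])
    report["stages"]["ranking"] = {
        "order": ranking.order,
        "ordering_string": ranking.ordering_string,
        "adjusted_p": {
            f"{a}|{b}": round(float(ranking.adjusted_p.loc[a, b]), 6)
            for i, a in enumerate(ranking.order)
            for b in ranking.order[i + 1 :]
        },
    }
    report["warnings"].extend(ranking.warnings)
    if out is not None:
        ranking.adjusted_p.to_csv(out / "pairwise_adjusted_p.tsv", sep="\t")
    done(s)

    # -- CNV screen ----------------------------------------------------
    s = stage("cnv")
    cnv_cfg = cfg.get("cnv")
    if not cnv_cfg:
        report["stages"]["cnv"] = {"skipped": "no cnv block in config"}
    else:
        ref_samples = set(cnv_cfg["reference_samples"])
        ref_cells = matrix.cells.index[matrix.cells["sample"].isin(ref_samples)]
        calls_out = []
        for target in cnv_cfg["targets"]:
            tname = target.get("name") or target.get("cell_type") or target.get("sample")
            if "cell_type" in target:
                mask = (cell_types == target["cell_type"]).reindex(
                    matrix.barcodes, fill_value=False
                )
            else:
                mask = matrix.cells["sample"] == target["sample"]
            tcells = matrix.cells.index[mask]
            calls, _ = cnv_screen.screen(
                matrix,
                tcells,
                ref_cells,
                window=int(cnv_cfg.get("window", 51)),
                threshold=float(cnv_cfg.get("threshold", 0.3)),
                target_group=str(tname),
            )
            calls_out.extend(
                {
                    "target_group": c.target_group,
                    "arm": c.arm,
                    "direction": c.direction,
                    "score": round(c.score, 4),
                    "n_genes": c.n_genes,
                }
                for c in calls
            )
        report["stages"]["cnv"] = {"calls": calls_out}
        if out is not None:
            pd.DataFrame(calls_out).to_csv(out / "cnv_calls.tsv", sep="\t", index=False)
    done(s)

    # -- correlation signatures ----------------------------------------
    s = stage("signatures")
    infected = matrix.cells["status"] == "infected"
    ctl = ~infected
    inf_groups = cell_types[infected.to_numpy()].dropna()
    inf_groups = inf_groups[inf_groups != cell_annotation.UNCLASSIFIED]
    ctl_groups = cell_types[ctl.to_numpy()].dropna()
    ctl_groups = ctl_groups[ctl_groups != cell_annotation.UNCLASSIFIED]

    inf_means = cs.group_mean_expression(matrix, inf_groups, min_cells=cfg["min_group"])
    grp = profile.groups.xs("infected", level="status")["mean_fraction"]
    viral_means = grp[grp.index.intersection(inf_means.columns)]
    inf_means = inf_means[viral_means.index]

    post_records = cs.correlate_with_viral_load(inf_means, viral_means)
    post_sig = cs.select_signatures(
        post_records, r_threshold=cfg["r_threshold"], top_n=cfg["top_n"]
    )

    pre_info: dict[str, Any]
    try:
        ctl_means = cs.group_mean_expression(
            matrix, ctl_groups, min_cells=cfg["min_group"]
        )
        matching = {t: t for t in ctl_means.columns if t in viral_means.index}
        pre_records = cs.pre_infection_correlation(ctl_means, viral_means, matching)
        pre_sig = cs.select_signatures(
            pre_records, r_threshold=cfg["r_threshold"], top_n=cfg["top_n"]
        )
        shared_pos, shared_neg = cs.shared_signature_genes(pre_sig, post_sig)
        pre_info = {
            "n_positive": len(pre_sig.positive),
            "n_negative": len(pre_sig.negative),
            "shared_positive": shared_pos,
            "shared_negative": shared_neg,
        }
        if out is not None:
            pre_records.to_csv(out / "correlations_pre.tsv", sep="\t")
    except Exception as exc:  # pre-infection arm is optional in the data
        pre_info = {"skipped": f"pre-infection correlation unavailable: {exc}"}
    report["stages"]["signatures"] = {
        "n_groups": int(len(viral_means)),
        "post": {
            "n_positive": len(post_sig.positive),
            "n_negative": len(post_sig.negative),
            "top_positive": post_sig.positive[:25],
            "top_negative": post_sig.negative[:25],
        },
        "pre": pre_info,
    }
    if out is not None:
        post_records.to_csv(out / "correlations_post.tsv", sep="\t")
        pd.Series(post_sig.positive, name="gene_id").to_csv(
            out / "signature_positive.tsv", sep="\t", index=False
        )
        pd.Series(post_sig.negative, name="gene_id").to_csv(
            out / "signature_negative.tsv", sep="\t", index=False
        )
    done(s)

    # -- differential expression ---------------------------------------
    s = stage("differential_expression")
    try:
        de = cs.differential_expression(matrix, cell_types, min_cells=cfg["min_group"])
        report["stages"]["differential_expression"] = {
            "types_tested": sorted(de.per_type),
            "types_skipped": de.skipped_types,
            "top_common_upregulated": list(de.common_upregulated.index[:50]),
        }
        if out is not None:
            de.common_upregulated.to_csv(out / "de_common_upregulated.tsv", sep="\t")
            for t, df in de.per_type.items():
                df.to_csv(out / f"de_{t}.tsv", sep="\t")
    except Exception as exc:
        report["stages"]["differential_expression"] = {"skipped": str(exc)}
    done(s)

    # -- viral genes ---------------------------------------------------
    s = stage("viral_genes")
    vrec = vga.correlate_viral_genes(
        matrix, inf_groups, viral_means, min_cells=cfg["min_group"]
    )
    ok, offending = vga.check_no_negative(vrec, r_threshold=cfg["r_threshold"])
    tally = vga.tally_temporal_classes(vrec[vrec["R"] > cfg["r_threshold"]])
    fixture = vga.load_table_fixture()
    ftally = vga.tally_temporal_classes(fixture)
    report["stages"]["viral_genes"] = {
        "n_correlated_above_threshold": int((vrec["R"] > cfg["r_threshold"]).sum()),
        "no_negative_correlates": bool(ok),
        "negative_correlates": list(offending["gene"]) if not ok else [],
        "tally_above_threshold": {
            "Early": tally.early,
            "Late": tally.late,
            "EarlyLate": tally.early_late,
            "Unknown": tally.unknown,
            "n_known": tally.n_known,
        },
        "reference_table_tally": {
            "Early": ftally.early,
            "Late": ftally.late,
            "EarlyLate": ftally.early_late,
            "Unknown": ftally.unknown,
            "n_known": ftally.n_known,
        },
    }
    if out is not None:
        vrec.to_csv(out / "viral_gene_correlations.tsv", sep="\t")
    done(s)

    report["timings_s"] = timings
    report["timestamp"] = datetime.now(timezone.utc).isoformat()
    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report
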