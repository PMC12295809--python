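"""Ground-truth-labelled synthetic single-cell infection datasets.

Generative model (all draws from one seeded generator, in a fixed,
documented order so adding a config field never reshuffles earlier draws):

1. host per-gene base rates ~ Gamma(shape=1.5, scale=1);
2. viral per-gene allocation weights ~ Gamma(1.5, 1), temporal classes
   drawn per gene (Early-heavy, mirroring poxvirus biology), and
   "early"-class weights multiplied by ``early_weight``;
3. marker genes per cell type, then planted correlation genes (positive,
   negative, infected-only variants) and infection-induced genes, all
   drawn without replacement from the upper half of base rates
   (curated markers and detectable signature genes are well expressed);
4. per sample: cell types ~ multinomial(type_proportions); library sizes
   L ~ round(LogNormal(library_size_log_mean, library_size_log_sd));
   for infected samples a per-cell viral fraction
   v ~ Beta(mean=viral_mean_fraction[type], concentration=viral_dispersion);
   round(v*L) counts are allocated multinomially over viral-gene weights
   and the remaining L - round(v*L) counts multinomially over the
   type/status-specific host gene rates.

Host rates per (type, status): markers of the type x ``marker_fold``;
planted positive genes x exp(planted_effect * (mu_type - mu_bar)) with
mu_type the type's configured viral mean and mu_bar the across-type mean
(negative genes use -planted_effect); infected-only planted genes apply
the same multiplier in infected cells only; induced genes x
``induced_fold`` in infected cells; CNV events multiply every gene on the
named arm in the named type by the event's fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from virocell.config import SyntheticConfig
from virocell.datatypes import (
    VIRUS_CONTIG,
    ExpressionMatrix,
    MarkerDB,
)
from virocell.errors import ConfigurationError

#: Probabilities of viral temporal classes (Early, Late, EarlyLate, Unknown).
TEMPORAL_CLASS_PROBS = {
    "Early": 0.45,
    "Late": 0.30,
    "EarlyLate": 0.10,
    "Unknown": 0.15,
}

_GAMMA_SHAPE = 1.5
_BP_PER_GENE = 10_000


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    cell_types: pd.Series  # barcode -> true type
    planted_pos: list[str]
    planted_neg: list[str]
    planted_pos_infected_only: list[str] = field(default_factory=list)
    planted_neg_infected_only: list[str] = field(default_factory=list)
    induced_genes: list[str] = field(default_factory=list)
    markers: dict[str, list[str]] = field(default_factory=dict)  # type -> symbols
    cnv_events: list = field(default_factory=list)
    viral_mean_fraction: dict[str, float] = field(default_factory=dict)
    config: SyntheticConfig | None = None

    def marker_db(self) -> MarkerDB:
        return MarkerDB(positive={t: set(m) for t, m in self.markers.items()})

    def expected_order(self) -> list[str]:
        """Infected-group ordering implied by the configured viral means."""
        present = sorted(set(self.cell_types))
        return sorted(
            (t for t in present if t in self.viral_mean_fraction),
            key=lambda t: (-self.viral_mean_fraction[t], t),
        )


def _build_gene_table(cfg: SyntheticConfig, rng: np.random.Generator):
    """Host genes in contiguous arm blocks + viral genes on the VV contig."""
    arms = []
    for chrom in range(1, 23):
        arms.append((str(chrom), f"{chrom}p"))
        arms.append((str(chrom), f"{chrom}q"))
    rows = []
    for i in range(cfg.n_host_genes):
        block = i // cfg.genes_per_arm
        chrom, arm = arms[block % len(arms)]
        within = i % cfg.genes_per_arm + (block // len(arms)) * cfg.genes_per_arm
        rows.append(
            {
                "gene_id": f"host_{i:05d}",
                "symbol": f"HG{i:05d}",
                "origin": "host",
                "chromosome": chrom,
                "arm": arm,
                "start": within * _BP_PER_GENE,
                "functional_class": None,
                "temporal_class": None,
            }
        )
    classes = list(TEMPORAL_CLASS_PROBS)
    probs = np.array([TEMPORAL_CLASS_PROBS[c] for c in classes])
    viral_classes = rng.choice(classes, size=cfg.n_viral_genes, p=probs)
    for j in range(cfg.n_viral_genes):
        rows.append(
            {
                "gene_id": f"viral_{j:03d}",
                "symbol": f"VV{j:03d}",
                "origin": "viral",
                "chromosome": VIRUS_CONTIG,
                "arm": VIRUS_CONTIG,
                "start": j * 1000,
                "functional_class": None,
                "temporal_class": str(viral_classes[j]),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id"), viral_classes


def _pick(rng: np.random.Generator, pool: list[int], k: int) -> list[int]:
    if k > len(pool):
        raise ConfigurationError(
            f"cannot draw {k} special genes from a pool of {len(pool)}"
        )
    chosen = rng.choice(len(pool), size=k, replace=False) if k else np.empty(0, int)
    chosen_idx = sorted(int(pool[i]) for i in chosen)
    remaining = sorted(set(pool) - set(chosen_idx))
    pool[:] = remaining
    return chosen_idx


def generate_dataset(cfg: SyntheticConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate one synthetic dataset plus its ground truth labels."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # 1. host base rates
    host_rates = rng.gamma(_GAMMA_SHAPE, 1.0, size=cfg.n_host_genes)

    # 2. viral gene weights and temporal classes
    viral_weights = rng.gamma(_GAMMA_SHAPE, 1.0, size=cfg.n_viral_genes)
    genes, viral_classes = _build_gene_table(cfg, rng)
    viral_weights = viral_weights * np.where(
        viral_classes == "Early", cfg.early_weight, 1.0
    )
    viral_p = viral_weights / viral_weights.sum()

    # 3. special gene selection from the well-expressed (upper-half) pool
    pool = sorted(np.flatnonzero(host_rates >= np.median(host_rates)).tolist())
    types = cfg.cell_types()
    marker_idx: dict[str, list[int]] = {
        t: _pick(rng, pool, cfg.markers_per_type) for t in types
    }
    pos_idx = _pick(rng, pool, cfg.n_pos_planted)
    neg_idx = _pick(rng, pool, cfg.n_neg_planted)
    pos_io_idx = _pick(rng, pool, cfg.n_pos_infected_only)
    neg_io_idx = _pick(rng, pool, cfg.n_neg_infected_only)
    induced_idx = _pick(rng, pool, cfg.n_induced)

    host_ids = genes.index[: cfg.n_host_genes]
    mu = cfg.viral_mean_fraction
    mu_bar = float(np.mean([mu[t] for t in types]))

    def host_probs(cell_type: str, infected: bool) -> np.ndarray:
        rates = host_rates.copy()
        rates[marker_idx[cell_type]] *= cfg.marker_fold
        delta = mu[cell_type] - mu_bar
        rates[pos_idx] *= np.exp(cfg.planted_effect * delta)
        rates[neg_idx] *= np.exp(-cfg.planted_effect * delta)
        if infected:
            rates[pos_io_idx] *= np.exp(cfg.planted_effect * delta)
            rates[neg_io_idx] *= np.exp(-cfg.planted_effect * delta)
            rates[induced_idx] *= cfg.induced_fold
        for ev in cfg.cnv_events:
            if ev.cell_type == cell_type:
                on_arm = (genes["arm"].to_numpy()[: cfg.n_host_genes] == ev.arm)
                rates[on_arm] *= ev.fold
        return rates / rates.sum()

    # annotate functional classes for bookkeeping
    genes["functional_class"] = None
    fclass = genes["functional_class"].copy()
    for t, idx in marker_idx.items():
        fclass.iloc[idx] = f"marker:{t}"
    genes["functional_class"] = fclass

    n_genes = cfg.n_host_genes + cfg.n_viral_genes
    blocks: list[sp.csr_matrix] = []
    barcodes: list[str] = []
    cell_rows: list[dict] = []
    true_types: list[str] = []

    # 4. per-sample draws, samples in configured order
    for sample in cfg.samples:
        props = cfg.proportions_for(sample.name)
        tnames = sorted(props)
        p = np.array([props[t] for t in tnames], dtype=float)
        n = cfg.n_cells_per_sample
        cell_types = rng.choice(tnames, size=n, p=p)
        libs = np.maximum(
            1,
            np.rint(
                rng.lognormal(cfg.library_size_log_mean, cfg.library_size_log_sd, n)
            ).astype(np.int64),
        )
        if sample.infected:
            means = np.array([mu[t] for t in cell_types])
            v = np.zeros(n)
            nonzero = means > 0
            a = means[nonzero] * cfg.viral_dispersion
            b = (1.0 - means[nonzero]) * cfg.viral_dispersion
            v[nonzero] = rng.beta(a, b)
        else:
            v = np.zeros(n)
        viral_counts = np.rint(v * libs).astype(np.int64)
        host_counts = libs - viral_counts

        counts = np.zeros((n, n_genes), dtype=np.int64)
        for t in tnames:
            sel = np.flatnonzero(cell_types == t)
            if not len(sel):
                continue
            hp = host_probs(t, sample.infected)
            counts[np.ix_(sel, np.arange(cfg.n_host_genes))] = rng.multinomial(
                host_counts[sel], hp
            )
            if viral_counts[sel].sum():
                counts[np.ix_(sel, np.arange(cfg.n_host_genes, n_genes))] = (
                    rng.multinomial(viral_counts[sel], viral_p)
                )
        blocks.append(sp.csr_matrix(counts))
        for i in range(n):
            bc = f"{sample.name}_{i:05d}"
            barcodes.append(bc)
            cell_rows.append(
                {
                    "barcode": bc,
                    "sample": sample.name,
                    "status": "infected" if sample.infected else "control",
                    "assigned_type": None,
                    "cluster": None,
                }
            )
        true_types.extend(cell_types.tolist())

    matrix = ExpressionMatrix(
        sp.vstack(blocks).tocsr(),
        genes,
        pd.DataFrame(cell_rows).set_index("barcode"),
    )
    truth = GroundTruth(
        cell_types=pd.Series(true_types, index=pd.Index(barcodes, name="barcode")),
        planted_pos=list(host_ids[pos_idx]),
        planted_neg=list(host_ids[neg_idx]),
        planted_pos_infected_only=list(host_ids[pos_io_idx]),
        planted_neg_infected_only=list(host_ids[neg_io_idx]),
        induced_genes=list(host_ids[induced_idx]),
        markers={
            t: list(genes["symbol"].iloc[idx]) for t, idx in marker_idx.items()
        },
        cnv_events=list(cfg.cnv_events),
        viral_mean_fraction={t: mu[t] for t in types},
        config=cfg,
    )
    return matrix, truth
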