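"""Configuration of the synthetic multi-culture infection experiment.

Defaults emulate the study design the analysis expects: five brain cell
cultures (two glioblastoma-derived, one gliosis, one normal brain, one
immortalized line), each measured as a control and a virus-infected sample
("v" suffix), with ~8 cell types whose mean viral transcript fraction
spans roughly 0.02-0.30 at a fixed time point after low-MOI infection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from virocell.errors import ConfigurationError

#: Cell-type labels used by the default configuration.
DEFAULT_TYPES = ("PN", "CL", "UN", "Mgl", "Fib", "Prc", "OC", "U87")

#: Default mean viral transcript fraction per type for infected samples,
#: ordered PN > Mgl > UN > Fib > U87 > Prc > OC > CL.
DEFAULT_VIRAL_MEANS = {
    "PN": 0.30,
    "Mgl": 0.24,
    "UN": 0.16,
    "Fib": 0.13,
    "U87": 0.10,
    "Prc": 0.07,
    "OC": 0.04,
    "CL": 0.02,
}

#: Default per-culture cell-type composition. Malignant subtypes appear
#: only in their tumour culture; non-malignant cultures carry stromal types.
DEFAULT_CULTURE_COMPOSITION = {
    "HB1": {"Fib": 0.40, "Mgl": 0.25, "Prc": 0.20, "OC": 0.15},
    "HB3": {"PN": 0.30, "UN": 0.25, "Fib": 0.15, "Mgl": 0.15, "Prc": 0.10, "OC": 0.05},
    "HB4": {"CL": 0.45, "Fib": 0.20, "Mgl": 0.15, "Prc": 0.12, "OC": 0.08},
    "NB": {"Fib": 0.35, "Mgl": 0.30, "Prc": 0.20, "OC": 0.15},
    "U87": {"U87": 1.0},
}


@dataclass(frozen=True)
class SampleSpec:
    """One sequencing sample: a culture, infected or control."""

    name: str
    infected: bool


@dataclass(frozen=True)
class CnvEventSpec:
    """A planted arm-level dosage event in one malignant cell type."""

    cell_type: str
    arm: str
    fold: float  # <1 loss, >1 gain

    @property
    def direction(self) -> str:
        return "gain" if self.fold > 1 else "loss"


def _default_samples() -> list[SampleSpec]:
    out = []
    for culture in DEFAULT_CULTURE_COMPOSITION:
        out.append(SampleSpec(culture, False))
        out.append(SampleSpec(culture + "v", True))
    return out


def _default_cnv_events() -> list[CnvEventSpec]:
    events = []
    for t in ("PN", "UN"):  # HB3-like malignant cells: loss of chr19 and 22q
        for arm in ("19p", "19q", "22q"):
            events.append(CnvEventSpec(t, arm, 0.5))
    # HB4-like classical cells: gain of chr7, loss of 15p
    events.append(CnvEventSpec("CL", "7p", 1.5))
    events.append(CnvEventSpec("CL", "7q", 1.5))
    events.append(CnvEventSpec("CL", "15p", 0.5))
    return events


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic single-cell infection dataset."""

    seed: int = 0
    n_cells_per_sample: int = 500
    samples: list[SampleSpec] = field(default_factory=_default_samples)
    #: map sample (or culture) name -> {cell type -> fraction}; a flat
    #: {type -> fraction} map is applied to every sample.
    type_proportions: dict[str, Any] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CULTURE_COMPOSITION.items()}
    )
    viral_mean_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VIRAL_MEANS)
    )
    viral_dispersion: float = 50.0
    library_size_log_mean: float = math.log(5000.0)
    library_size_log_sd: float = 0.35
    n_host_genes: int = 2200
    n_viral_genes: int = 100
    genes_per_arm: int = 50
    n_pos_planted: int = 30
    n_neg_planted: int = 30
    planted_effect: float = 1.0
    cnv_events: list[CnvEventSpec] = field(default_factory=_default_cnv_events)
    markers_per_type: int = 5
    marker_fold: float = 8.0
    early_weight: float = 3.0
    #: moi is experiment metadata only; it does not enter the generative model
    moi_pfu_per_cell: float = 0.1
    # genes whose viral-load coupling exists only in infected cells
    n_pos_infected_only: int = 0
    n_neg_infected_only: int = 0
    # genes induced by infection irrespective of viral load
    n_induced: int = 0
    induced_fold: float = 4.0

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.n_cells_per_sample <= 0:
            raise ConfigurationError("n_cells_per_sample must be positive")
        if not self.samples:
            raise ConfigurationError("samples must be non-empty")
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ConfigurationError("samples: duplicate sample names")
        for sample in self.samples:
            props = self.proportions_for(sample.name)
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"type_proportions for sample {sample.name!r} sum to {total}, not 1"
                )
            for t, p in props.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"type_proportions[{t!r}] = {p} outside [0, 1]"
                    )
                if t not in self.viral_mean_fraction:
                    raise ConfigurationError(
                        f"viral_mean_fraction missing cell type {t!r}"
                    )
        for t, v in self.viral_mean_fraction.items():
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(
                    f"viral_mean_fraction[{t!r}] = {v} outside [0, 1)"
                )
        if self.viral_dispersion <= 0:
            raise ConfigurationError("viral_dispersion must be positive")
        n_special = (
            self.n_pos_planted
            + self.n_neg_planted
            + self.n_pos_infected_only
            + self.n_neg_infected_only
            + self.n_induced
        )
        if n_special + self.markers_per_type * len(self.cell_types()) > self.n_host_genes // 2:
            raise ConfigurationError(
                "n_pos_planted/n_neg_planted/markers exceed the well-expressed "
                f"half of n_host_genes ({self.n_host_genes})"
            )
        if self.early_weight < 1.0:
            raise ConfigurationError("early_weight must be >= 1")
        if self.n_viral_genes < 1:
            raise ConfigurationError("n_viral_genes must be >= 1")

    def cell_types(self) -> list[str]:
        """All cell types used by any sample, sorted."""
        types: set[str] = set()
        for sample in self.samples:
            types |= set(self.proportions_for(sample.name))
        return sorted(types)

    def proportions_for(self, sample_name: str) -> dict[str, float]:
        """Resolve the type-proportion map for one sample.

        Accepts per-sample maps keyed by sample name or by culture name
        (sample name with the trailing "v" stripped), or one flat map.
        """
        tp = self.type_proportions
        if tp and all(isinstance(v, dict) for v in tp.values()):
            if sample_name in tp:
                return tp[sample_name]
            base = sample_name[:-1] if sample_name.endswith("v") else sample_name
            if base in tp:
                return tp[base]
            raise ConfigurationError(
                f"type_proportions has no entry for sample {sample_name!r}"
            )
        return {str(k): float(v) for k, v in tp.items()}

    # -- (de)serialisation --------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("samples", "cnv_events")
        }
        d["samples"] = [{"name": s.name, "infected": s.infected} for s in self.samples]
        d["cnv_events"] = [
            {"cell_type": e.cell_type, "arm": e.arm, "fold": e.fold}
            for e in self.cnv_events
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SyntheticConfig":
        d = dict(d)
        if "samples" in d:
            d["samples"] = [
                SampleSpec(s["name"], bool(s["infected"])) for s in d["samples"]
            ]
        if "cnv_events" in d:
            d["cnv_events"] = [
                CnvEventSpec(e["cell_type"], e["arm"], float(e["fold"]))
                for e in d["cnv_events"]
            ]
        unknown = set(d) - set(cls().__dict__)
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def load_config(path: str | Path) -> SyntheticConfig:
    """Load a :class:`SyntheticConfig` from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must hold a mapping")
    return SyntheticConfig.from_dict(data)


def save_config(cfg: SyntheticConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
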