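"""Shared setup for the analysis scripts: the study-scale synthetic dataset.

Five brain cell cultures (two glioblastoma-derived, one gliosis, one
normal brain, one immortalized line), each as a control and an infected
sample, 500 cells per sample. Malignant types carry arm-level CNVs
(chr19/22q losses in the proneural culture, chr7 gain and 15p loss in
the classical one); 30 + 30 host genes are coupled positively/negatively
to type-level viral load, and 10 genes are induced by infection itself.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path

from virocell.config import SyntheticConfig
from virocell.synthetic import generate_dataset

STUDY_SEED = 1

RESULTS = Path(__file__).resolve().parents[1] / "results"


def study_config() -> SyntheticConfig:
    return SyntheticConfig(seed=STUDY_SEED, n_induced=10, induced_fold=4.0)


@lru_cache(maxsize=1)
def study_dataset():
    """Generate (once) the study dataset and its ground truth."""
    return generate_dataset(study_config())


def outdir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
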