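"""Shared fixtures: hand-built matrices and small synthetic datasets."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from virocell.config import SampleSpec, SyntheticConfig
from virocell.datatypes import ExpressionMatrix
from virocell.synthetic import generate_dataset


def tiny_matrix() -> ExpressionMatrix:
    """3 cells x 4 genes (3 host + 1 viral) with hand-typed counts."""
    counts = np.array(
        [
            [5, 0, 3, 2],  # 10 total, 2 viral
            [0, 4, 0, 0],  # all host
            [1, 1, 2, 4],  # 8 total, 4 viral
        ]
    )
    genes = pd.DataFrame(
        {
            "symbol": ["GA", "GB", "GC", "VV001"],
            "origin": ["host", "host", "host", "viral"],
            "chromosome": ["1", "1", "2", "VV"],
            "arm": ["1p", "1p", "2q", "VV"],
            "start": [0, 10000, 0, 0],
            "functional_class": [None] * 4,
            "temporal_class": [None, None, None, "Early"],
        },
        index=pd.Index(["g1", "g2", "g3", "v1"], name="gene_id"),
    )
    cells = pd.DataFrame(
        {
            "sample": ["Av", "B", "Av"],
            "status": ["infected", "control", "infected"],
            "assigned_type": ["T1", "T2", "T1"],
            "cluster": [0, 1, 0],
        },
        index=pd.Index(["c1", "c2", "c3"], name="barcode"),
    )
    return ExpressionMatrix(sp.csr_matrix(counts), genes, cells)


@pytest.fixture
def hand_matrix() -> ExpressionMatrix:
    return tiny_matrix()


def pure_type_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Six infected single-type samples with viral means spanning 0.02-0.30."""
    types = ["T1", "T2", "T3", "T4", "T5", "T6"]
    means = dict(zip(types, [0.30, 0.22, 0.16, 0.11, 0.06, 0.02]))
    base = dict(
        seed=seed,
        n_cells_per_sample=300,
        samples=[SampleSpec(t + "v", True) for t in types],
        type_proportions={t + "v": {t: 1.0} for t in types},
        viral_mean_fraction=means,
        n_host_genes=600,
        n_viral_genes=60,
        genes_per_arm=50,
        n_pos_planted=20,
        n_neg_planted=20,
        planted_effect=1.0,
        cnv_events=[],
        markers_per_type=3,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def culture_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Reduced-size version of the default five-culture experiment."""
    base = dict(
        seed=seed,
        n_cells_per_sample=150,
        n_host_genes=880,
        n_viral_genes=40,
        genes_per_arm=20,
        n_pos_planted=15,
        n_neg_planted=15,
        markers_per_type=4,
        library_size_log_mean=math.log(3000.0),
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def culture_dataset():
    """One small five-culture dataset with ground truth, reused read-only."""
    cfg = culture_config(seed=11)
    return generate_dataset(cfg)
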