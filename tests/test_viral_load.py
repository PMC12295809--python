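"""Viral fraction arithmetic, Holm adjustment, susceptibility ranking."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from virocell.datatypes import ExpressionMatrix
from virocell.errors import ConfigurationError, ValidationError
from virocell.synthetic import generate_dataset
from virocell.viral_load import (
    holm_bonferroni,
    rank_susceptibility,
    summarize_groups,
    viral_fraction,
)

from conftest import pure_type_config, tiny_matrix


class TestViralFraction:
    def test_forced_arithmetic(self, hand_matrix):
        frac, n_dropped = viral_fraction(hand_matrix)
        assert n_dropped == 0
        assert frac["c1"] == pytest.approx(2 / 10)
        assert frac["c2"] == 0.0  # host-only cell
        assert frac["c3"] == pytest.approx(4 / 8)

    def test_cell_with_50_of_200_viral(self):
        m = tiny_matrix()
        counts = np.array([[150, 0, 0, 50], [1, 0, 0, 0], [1, 0, 0, 0]])
        m2 = ExpressionMatrix(sp.csr_matrix(counts), m.genes, m.cells)
        frac, _ = viral_fraction(m2)
        assert frac["c1"] == pytest.approx(0.25)

    def test_no_viral_genes_is_a_configuration_error(self, hand_matrix):
        host_only = ExpressionMatrix(
            hand_matrix.counts[:, :3], hand_matrix.genes.iloc[:3], hand_matrix.cells
        )
        with pytest.raises(ConfigurationError):
            viral_fraction(host_only)

    def test_zero_total_cells_dropped_and_counted(self, hand_matrix):
        counts = hand_matrix.counts.toarray()
        counts[1] = 0
        m2 = ExpressionMatrix(sp.csr_matrix(counts), hand_matrix.genes, hand_matrix.cells)
        frac, n_dropped = viral_fraction(m2)
        assert n_dropped == 1 and "c2" not in frac.index

    def test_fraction_invariant_to_count_scaling(self, hand_matrix):
        frac, _ = viral_fraction(hand_matrix)
        scaled = ExpressionMatrix(
            hand_matrix.counts * 7, hand_matrix.genes, hand_matrix.cells
        )
        frac2, _ = viral_fraction(scaled)
        pd.testing.assert_series_equal(frac, frac2)

    def test_recovers_configured_type_means(self):
        matrix, truth = generate_dataset(pure_type_config(seed=2))
        frac, _ = viral_fraction(matrix)
        prof = summarize_groups(frac, matrix.cells, cell_types=truth.cell_types)
        means = prof.groups.xs("infected", level="status")["mean_fraction"]
        for t, mu in truth.viral_mean_fraction.items():
            assert abs(means[t] - mu) < 0.02


class TestSummarizeGroups:
    def test_mean_matches_hand_groupby(self, hand_matrix):
        frac, _ = viral_fraction(hand_matrix)
        prof = summarize_groups(frac, hand_matrix.cells, min_group_size=2)
        # T1/infected: cells c1 (0.2) and c3 (0.5)
        row = prof.groups.loc[("T1", "infected")]
        assert row["mean_fraction"] == pytest.approx(np.mean([0.2, 0.5]))
        assert row["median_fraction"] == pytest.approx(np.median([0.2, 0.5]))
        assert prof.groups["n_cells"].sum() == hand_matrix.n_cells

    def test_single_cell_group_flagged_low_confidence(self, hand_matrix):
        frac, _ = viral_fraction(hand_matrix)
        prof = summarize_groups(frac, hand_matrix.cells, min_group_size=20)
        assert bool(prof.groups.loc[("T2", "control"), "low_confidence"])

    def test_unassigned_cells_grouped_as_other(self, hand_matrix):
        cells = hand_matrix.cells.copy()
        cells["assigned_type"] = [None, "T2", None]
        m2 = ExpressionMatrix(hand_matrix.counts, hand_matrix.genes, cells)
        frac, _ = viral_fraction(m2)
        prof = summarize_groups(frac, m2.cells)
        assert ("other", "infected") in prof.groups.index


class TestHolmBonferroni:
    def test_worked_example(self):
        np.testing.assert_allclose(
            holm_bonferroni([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04]
        )

    def test_single_value_identity(self):
        np.testing.assert_allclose(holm_bonferroni([0.5]), [0.5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_definition_and_statsmodels(self, pvals):
        adj = holm_bonferroni(pvals)
        # brute-force step-down definition
        p = np.asarray(pvals)
        order = np.argsort(p, kind="stable")
        m = len(p)
        expected = np.empty(m)
        running = 0.0
        for rank, j in enumerate(order):
            running = max(running, min(1.0, (m - rank) * p[j]))
            expected[j] = running
        np.testing.assert_allclose(adj, expected)
        np.testing.assert_allclose(adj, multipletests(p, method="holm")[1])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_bounded_and_dominates_raw(self, pvals):
        p = np.asarray(pvals)
        adj = holm_bonferroni(p)
        assert np.all(adj <= 1.0) and np.all(adj >= p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            holm_bonferroni([0.5, 1.2])


class TestRanking:
    @staticmethod
    def profile_from(fractions_by_group):
        rows = []
        for g, values in fractions_by_group.items():
            for i, v in enumerate(values):
                rows.append((f"{g}{i}", v, g, "infected"))
        per_cell = pd.DataFrame(
            rows, columns=["barcode", "viral_fraction", "cell_type", "status"]
        ).set_index("barcode")
        frac = per_cell["viral_fraction"]
        from virocell.viral_load import ViralLoadProfile

        groups = per_cell.groupby(["cell_type", "status"])["viral_fraction"].agg(
            n_cells="size", mean_fraction="mean", median_fraction="median"
        )
        groups["low_confidence"] = False
        return ViralLoadProfile(per_cell=per_cell, groups=groups)

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        x = rng.beta(3, 10, size=200)
        prof = self.profile_from({"A": x, "B": x})
        ranking = rank_susceptibility(prof, alpha=0.01)
        assert ">>" not in ranking.ordering_string
        a, b = ranking.order
        assert ranking.adjusted_p.loc[a, b] > 0.9

    def test_recovers_configured_order_and_extremes(self):
        matrix, truth = generate_dataset(pure_type_config(seed=4))
        frac, _ = viral_fraction(matrix)
        prof = summarize_groups(frac, matrix.cells, cell_types=truth.cell_types)
        ranking = rank_susceptibility(prof, alpha=0.01)
        assert ranking.order == truth.expected_order()
        top, bottom = ranking.order[0], ranking.order[-1]
        assert ranking.adjusted_p.loc[top, bottom] < 0.01

    def test_group_input_order_irrelevant(self):
        rng = np.random.default_rng(1)
        data = {
            "A": rng.beta(30, 70, 150),
            "B": rng.beta(10, 90, 150),
            "C": rng.beta(5, 95, 150),
        }
        r1 = rank_susceptibility(self.profile_from(data))
        shuffled = {k: data[k] for k in ["C", "A", "B"]}
        r2 = rank_susceptibility(self.profile_from(shuffled))
        assert r1.order == r2.order
        assert r1.ordering_string == r2.ordering_string
        pd.testing.assert_frame_equal(r1.adjusted_p, r2.adjusted_p)

    def test_degenerate_pair_warns_with_p_one(self):
        # two identical zero-variance groups: the t statistic is undefined
        prof = self.profile_from({"A": [0.1, 0.1, 0.1], "B": [0.1, 0.1, 0.1]})
        ranking = rank_susceptibility(prof)
        assert ranking.warnings
        assert ranking.adjusted_p.loc["A", "B"] == 1.0

    def test_fewer_than_two_groups_rejected(self):
        prof = self.profile_from({"A": [0.1, 0.2, 0.3]})
        with pytest.raises(ValidationError):
            rank_susceptibility(prof)
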