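"""Correlation signatures: group means, Pearson selection, pre/post, DE."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from virocell.correlation_signatures import (
    correlate_with_viral_load,
    differential_expression,
    group_mean_expression,
    pre_infection_correlation,
    select_signatures,
    shared_signature_genes,
)
from virocell.datatypes import ExpressionMatrix, SignatureSet
from virocell.errors import ValidationError
from virocell.synthetic import generate_dataset
from virocell.viral_load import summarize_groups, viral_fraction

from conftest import pure_type_config
from test_annotation import marker_matrix


def viral_means_of(matrix, truth):
    frac, _ = viral_fraction(matrix)
    prof = summarize_groups(frac, matrix.cells, cell_types=truth.cell_types)
    return prof.groups.xs("infected", level="status")["mean_fraction"]


class TestGroupMeanExpression:
    def test_identical_cells_mean_equals_single_cell(self):
        counts = np.tile([4, 0, 6, 2], (25, 1))
        m = marker_matrix(counts, ["G0", "G1", "G2", "G3"])
        groups = pd.Series(["A"] * 25, index=m.barcodes)
        means = group_mean_expression(m, groups, min_cells=5)
        single = np.log1p(np.array([4, 0, 6, 2]) / 12 * 1e4)
        np.testing.assert_allclose(means["A"].to_numpy(), single)

    def test_library_doubling_leaves_means_unchanged(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3, size=(30, 5))
        m1 = marker_matrix(counts, [f"G{i}" for i in range(5)])
        m2 = marker_matrix(counts * 2, [f"G{i}" for i in range(5)])
        groups = pd.Series(["A"] * 30, index=m1.barcodes)
        pd.testing.assert_frame_equal(
            group_mean_expression(m1, groups, min_cells=5),
            group_mean_expression(m2, groups, min_cells=5),
        )

    def test_hand_computed_four_cell_fixture(self):
        counts = np.array([[2, 8], [4, 16], [1, 0], [3, 0]])
        m = marker_matrix(counts, ["G0", "G1"])
        groups = pd.Series(["A", "A", "B", "B"], index=m.barcodes)
        means = group_mean_expression(m, groups, min_cells=2)
        # manual: CP10K per cell then log1p then mean per group
        a0 = np.mean([np.log1p(2 / 10 * 1e4), np.log1p(4 / 20 * 1e4)])
        b0 = np.mean([np.log1p(1 / 1 * 1e4), np.log1p(3 / 3 * 1e4)])
        assert means.loc["g0", "A"] == pytest.approx(a0)
        assert means.loc["g0", "B"] == pytest.approx(b0)

    def test_undersized_group_excluded(self):
        counts = np.ones((10, 3), dtype=int)
        m = marker_matrix(counts, ["G0", "G1", "G2"])
        groups = pd.Series(["A"] * 8 + ["B"] * 2, index=m.barcodes)
        means = group_mean_expression(m, groups, min_cells=5)
        assert list(means.columns) == ["A"]


class TestCorrelateWithViralLoad:
    def test_perfectly_linear_gene_r_one(self):
        y = pd.Series([0.02, 0.1, 0.15, 0.2, 0.3], index=list("ABCDE"))
        means = pd.DataFrame(
            {g: 2 * y[g] + 1 for g in y.index}, index=["lin"]
        )
        rec = correlate_with_viral_load(means, y)
        assert rec.loc["lin", "R"] == pytest.approx(1.0)

    def test_constant_gene_excluded_not_zero(self):
        y = pd.Series([0.1, 0.2, 0.3], index=list("ABC"))
        means = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]],
                             index=["flat", "lin"], columns=list("ABC"))
        rec = correlate_with_viral_load(means, y)
        assert "flat" not in rec.index and "lin" in rec.index

    def test_fewer_than_three_groups_rejected(self):
        y = pd.Series([0.1, 0.2], index=list("AB"))
        means = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=list("AB"))
        with pytest.raises(ValidationError):
            correlate_with_viral_load(means, y)

    def test_affine_transform_of_viral_axis_preserves_r(self):
        rng = np.random.default_rng(2)
        y = pd.Series(rng.uniform(0, 0.3, 6), index=list("ABCDEF"))
        means = pd.DataFrame(
            rng.normal(size=(40, 6)), columns=list("ABCDEF")
        )
        r1 = correlate_with_viral_load(means, y)["R"]
        r2 = correlate_with_viral_load(means, y * 100)["R"]
        r3 = correlate_with_viral_load(means, y * 100 + 7)["R"]
        pd.testing.assert_series_equal(r1, r2)
        pd.testing.assert_series_equal(r1, r3)

    def test_group_order_invariance(self):
        rng = np.random.default_rng(3)
        y = pd.Series(rng.uniform(0, 0.3, 5), index=list("ABCDE"))
        means = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("ABCDE"))
        r1 = correlate_with_viral_load(means, y)["R"]
        cols = list("CBEAD")
        r2 = correlate_with_viral_load(means[cols], y[cols])["R"]
        pd.testing.assert_series_equal(r1, r2)

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(4)
        y = pd.Series(rng.uniform(0, 0.3, 6), index=list("ABCDEF"))
        means = pd.DataFrame(rng.normal(size=(15, 6)), columns=list("ABCDEF"))
        rec = correlate_with_viral_load(means, y)
        for g in means.index:
            expected = stats.pearsonr(means.loc[g], y).statistic
            assert rec.loc[g, "R"] == pytest.approx(expected)

    def test_planted_genes_recovered(self):
        matrix, truth = generate_dataset(pure_type_config(seed=13))
        y = viral_means_of(matrix, truth)
        means = group_mean_expression(matrix, truth.cell_types)
        rec = correlate_with_viral_load(means[y.index], y)
        sig = select_signatures(rec)
        pos_hit = len(set(truth.planted_pos) & set(sig.positive))
        neg_hit = len(set(truth.planted_neg) & set(sig.negative))
        assert pos_hit / len(truth.planted_pos) >= 0.9
        assert neg_hit / len(truth.planted_neg) >= 0.9


class TestSelectSignatures:
    def test_all_below_threshold_empty(self):
        rec = pd.DataFrame({"R": [0.4, -0.3, 0.5, -0.5]}, index=list("abcd"))
        sig = select_signatures(rec)
        assert sig.positive == [] and sig.negative == []

    def test_truncation_to_top_n(self):
        rng = np.random.default_rng(0)
        rec = pd.DataFrame(
            {"R": rng.uniform(0.51, 1.0, 400)},
            index=[f"g{i:03d}" for i in range(400)],
        )
        sig = select_signatures(rec, top_n=300)
        assert len(sig.positive) == 300

    def test_equals_brute_force_filter_sort(self):
        rng = np.random.default_rng(1)
        rec = pd.DataFrame(
            {"R": rng.uniform(-1, 1, 200)}, index=[f"g{i:03d}" for i in range(200)]
        )
        sig = select_signatures(rec, r_threshold=0.5, top_n=50)
        pos = sorted(
            (g for g in rec.index if rec.loc[g, "R"] > 0.5),
            key=lambda g: (-rec.loc[g, "R"], g),
        )[:50]
        neg = sorted(
            (g for g in rec.index if rec.loc[g, "R"] < -0.5),
            key=lambda g: (rec.loc[g, "R"], g),
        )[:50]
        assert sig.positive == pos and sig.negative == neg


class TestPreInfection:
    def test_identical_means_reproduce_post_records(self):
        rng = np.random.default_rng(5)
        y = pd.Series(rng.uniform(0.02, 0.3, 5), index=list("ABCDE"))
        means = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("ABCDE"))
        post = correlate_with_viral_load(means, y)
        pre = pre_infection_correlation(means, y, {t: t for t in y.index})
        pd.testing.assert_series_equal(pre["R"], post["R"])
        assert (pre["mode"] == "pre_infection").all()

    def test_shuffled_matching_changes_r(self):
        rng = np.random.default_rng(6)
        y = pd.Series([0.02, 0.1, 0.2, 0.25, 0.3], index=list("ABCDE"))
        means = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("ABCDE"))
        straight = pre_infection_correlation(means, y, {t: t for t in y.index})
        rotated = dict(zip("ABCDE", "BCDEA"))
        shuffled = pre_infection_correlation(means, y, rotated)
        assert not np.allclose(straight["R"], shuffled["R"])

    def test_too_few_pairs_rejected(self):
        y = pd.Series([0.1, 0.2, 0.3], index=list("ABC"))
        means = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)),
                             columns=list("ABC"))
        with pytest.raises(ValidationError):
            pre_infection_correlation(means, y, {"A": "A", "B": "B"})

    def test_baseline_planted_genes_found_pre_infection(self):
        cfg = pure_type_config(
            seed=14,
            samples=pure_type_config().samples
            + [s.__class__(s.name[:-1], False) for s in pure_type_config().samples],
            type_proportions={
                **{t + "v": {t: 1.0} for t in ["T1", "T2", "T3", "T4", "T5", "T6"]},
                **{t: {t: 1.0} for t in ["T1", "T2", "T3", "T4", "T5", "T6"]},
            },
        )
        matrix, truth = generate_dataset(cfg)
        y = viral_means_of(matrix, truth)
        ctl = matrix.cells["status"] == "control"
        ctl_means = group_mean_expression(matrix, truth.cell_types[ctl.to_numpy()])
        pre = pre_infection_correlation(ctl_means, y, {t: t for t in y.index})
        sig = select_signatures(pre)
        hit = len(set(truth.planted_pos) & set(sig.positive))
        assert hit / len(truth.planted_pos) >= 0.9


class TestSharedSignatures:
    def test_disjoint_sets_share_nothing(self):
        pre = SignatureSet(positive=["a", "b"], negative=["x"])
        post = SignatureSet(positive=["c", "d"], negative=["y"])
        assert shared_signature_genes(pre, post) == ([], [])

    def test_simple_intersection_in_post_order(self):
        pre = SignatureSet(positive=["A", "B", "C"], negative=[])
        post = SignatureSet(positive=["B", "C", "D"], negative=[])
        shared_pos, shared_neg = shared_signature_genes(pre, post)
        assert shared_pos == ["B", "C"] and shared_neg == []

    def test_baseline_planted_shared_infected_only_not(self):
        """Genes whose coupling is baseline (present in control cells) appear
        in both pre and post signatures; infected-only coupled genes appear
        post-infection but not pre-infection."""
        types = ["T1", "T2", "T3", "T4", "T5", "T6"]
        cfg = pure_type_config(
            seed=15,
            n_pos_planted=2,
            n_neg_planted=0,
            n_pos_infected_only=3,
            samples=pure_type_config().samples
            + [s.__class__(s.name[:-1], False) for s in pure_type_config().samples],
            type_proportions={
                **{t + "v": {t: 1.0} for t in types},
                **{t: {t: 1.0} for t in types},
            },
        )
        matrix, truth = generate_dataset(cfg)
        y = viral_means_of(matrix, truth)
        inf = matrix.cells["status"] == "infected"
        post_means = group_mean_expression(matrix, truth.cell_types[inf.to_numpy()])
        ctl_means = group_mean_expression(matrix, truth.cell_types[(~inf).to_numpy()])
        post = select_signatures(correlate_with_viral_load(post_means[y.index], y))
        pre = select_signatures(
            pre_infection_correlation(ctl_means, y, {t: t for t in y.index})
        )
        shared_pos, _ = shared_signature_genes(pre, post)
        assert set(truth.planted_pos) <= set(shared_pos)
        assert set(truth.planted_pos_infected_only) <= set(post.positive)
        assert not set(truth.planted_pos_infected_only) & set(shared_pos)


class TestDifferentialExpression:
    @staticmethod
    def paired_config(seed=0, **overrides):
        types = ["T1", "T2", "T3"]
        base = dict(
            seed=seed,
            n_cells_per_sample=150,
            samples=[
                s
                for t in types
                for s in (
                    pure_type_config().samples[0].__class__(t + "v", True),
                    pure_type_config().samples[0].__class__(t, False),
                )
            ],
            type_proportions={
                **{t + "v": {t: 1.0} for t in types},
                **{t: {t: 1.0} for t in types},
            },
            viral_mean_fraction={"T1": 0.25, "T2": 0.1, "T3": 0.03},
            n_host_genes=400,
            n_viral_genes=30,
            genes_per_arm=50,
            n_pos_planted=0,
            n_neg_planted=0,
            cnv_events=[],
            markers_per_type=2,
            n_induced=8,
            induced_fold=4.0,
        )
        base.update(overrides)
        from virocell.config import SyntheticConfig

        return SyntheticConfig(**base)

    def test_induced_genes_top_common_upregulated(self):
        matrix, truth = generate_dataset(self.paired_config(seed=16))
        de = differential_expression(matrix, truth.cell_types)
        top50 = set(de.common_upregulated.index[:50])
        assert set(truth.induced_genes) <= top50
        for t, df in de.per_type.items():
            assert (df.loc[truth.induced_genes, "q"] < 0.05).all()
            assert (df.loc[truth.induced_genes, "log2_fc"] > 0).all()

    def test_identical_groups_single_gene_fold_change_zero(self):
        counts = np.ones((40, 1), dtype=int) * 3
        m = marker_matrix(counts, ["G0"], samples=["A"] * 20 + ["Bv"] * 20)
        types = pd.Series(["T"] * 40, index=m.barcodes)
        de = differential_expression(m, types, min_cells=10)
        assert de.per_type["T"].loc["g0", "log2_fc"] == 0.0
        assert de.per_type["T"].loc["g0", "q"] == 1.0

    def test_type_missing_one_arm_skipped(self):
        matrix, truth = generate_dataset(
            self.paired_config(seed=17, n_induced=0)
        )
        keep = matrix.cells["sample"] != "T3"
        sub = matrix.subset_cells(matrix.cells.index[keep])
        de = differential_expression(sub, truth.cell_types[keep.to_numpy()])
        assert "T3" in de.skipped_types and "T3" not in de.per_type
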