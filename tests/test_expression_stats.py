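"""Relative quantification, group tests, correlation, ROC, indices."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmlnet.expression_stats import (
    CTTable,
    PhenotypePanel,
    ddct,
    group_anova,
    homa_ir,
    insulin_ng_to_uU,
    pairwise_welch,
    pearson,
    read_phenotypes,
    roc_auc,
    tolerance_auc,
)


def ct_frame(rows):
    return CTTable(pd.DataFrame(rows, columns=["sample", "group", "target", "ct"]))


class TestDdct:
    def make_table(self):
        rows = []
        # calibrator group: two samples, dCT 7 each
        for s in ("c1", "c2"):
            rows += [(s, "Ctrl", "18SrRNA", 15.0), (s, "Ctrl", "geneX", 22.0)]
        # treated sample: dCT = 20 - 15 = 5, ddCT = -2, fold 4
        rows += [("t1", "HF-Sed", "18SrRNA", 15.0), ("t1", "HF-Sed", "geneX", 20.0)]
        return ct_frame(rows)

    def test_worked_example_fold_four(self):
        rel = ddct(self.make_table())
        t1 = rel[rel["sample"] == "t1"].iloc[0]
        assert t1["delta_delta_ct"] == pytest.approx(-2.0)
        assert t1["fold"] == pytest.approx(4.0)

    def test_calibrator_sample_at_group_mean_has_fold_one(self):
        rel = ddct(self.make_table())
        ctrl = rel[rel["group"] == "Ctrl"]
        assert ctrl["fold"].to_numpy() == pytest.approx([1.0, 1.0])

    @given(st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_constant_ct_shift_leaves_folds_unchanged(self, shift):
        base = self.make_table()
        shifted = CTTable(base.df.assign(ct=base.df["ct"] + shift))
        assert ddct(base)["fold"].to_numpy() == pytest.approx(
            ddct(shifted)["fold"].to_numpy()
        )

    def test_missing_reference_sample_skipped(self):
        table = self.make_table()
        extra = pd.DataFrame(
            [("t2", "HF-Sed", "geneX", 21.0)], columns=CTTable.COLUMNS
        )
        rel = ddct(CTTable(pd.concat([table.df, extra], ignore_index=True)))
        assert "t2" not in set(rel["sample"])

    def test_empty_calibrator_errors_naming_target(self):
        rows = [
            ("t1", "HF-Sed", "18SrRNA", 15.0),
            ("t1", "HF-Sed", "geneY", 20.0),
        ]
        with pytest.raises(ValueError, match="geneY"):
            ddct(ct_frame(rows))

    def test_missing_reference_assay_errors(self):
        rows = [("t1", "Ctrl", "geneX", 20.0)]
        with pytest.raises(ValueError, match="18SrRNA"):
            ddct(ct_frame(rows))


class TestAnova:
    def test_textbook_f_value(self):
        res = group_anova({"g1": [1, 2, 3], "g2": [4, 5, 6]})
        assert res.F == pytest.approx(13.5)
        assert res.group_means == {"g1": 2.0, "g2": 5.0}
        assert res.group_sems["g1"] == pytest.approx(1.0 / math.sqrt(3))

    def test_hand_sums_of_squares_oracle(self):
        rng = np.random.default_rng(6)
        groups = {f"g{i}": rng.normal(i, 1.0, size=8) for i in range(3)}
        res = group_anova(groups)
        all_vals = np.concatenate(list(groups.values()))
        grand = all_vals.mean()
        ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        dfb, dfw = len(groups) - 1, all_vals.size - len(groups)
        assert res.F == pytest.approx((ssb / dfb) / (ssw / dfw))

    def test_zero_variance_degenerate_reports_p_one(self):
        res = group_anova({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert res.p == 1.0

    def test_single_value_group_rejected(self):
        with pytest.raises(ValueError):
            group_anova({"a": [1.0], "b": [1.0, 2.0]})

    def test_null_p_uniform_under_permutation(self):
        """With identical group distributions, p is approximately uniform."""
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(300):
            vals = rng.normal(size=18)
            groups = {"a": vals[:6], "b": vals[6:12], "c": vals[12:]}
            pvals.append(group_anova(groups).p)
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_pairwise_welch_posthoc_shape(self):
        df = pairwise_welch({"a": [1, 2, 3], "b": [4, 5, 6], "c": [1, 2, 2]})
        assert len(df) == 3
        assert set(df.columns) >= {"group_a", "group_b", "t", "p", "p_adjusted"}


class TestPearson:
    def test_perfect_positive_linearity(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = pearson(x, [2 * v + 1 for v in x])
        assert res.r == pytest.approx(1.0)

    def test_perfect_negative_linearity(self):
        x = [1.0, 2.0, 3.0]
        assert pearson(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [5, 5, 5])

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])

    def test_planted_rho_recovered_within_sampling_bound(self):
        rho, n = 0.7, 500
        rng = np.random.default_rng(10)
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        res = pearson(xy[:, 0], xy[:, 1])
        assert abs(res.r - rho) <= 3 * (1 - rho**2) / math.sqrt(n)
        assert res.p < 1e-10


def auc_all_pairs(scores, labels):
    """Brute-force AUC: fraction of positive-negative pairs correctly
    ordered, ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], n_boot=200)
        assert res.auc == 1.0

    def test_all_ties_give_half(self):
        res = roc_auc([5.0] * 8, [0, 1] * 4, n_boot=200)
        assert res.auc == 0.5

    def test_matches_all_pairs_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(6, 25))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            res = roc_auc(scores, labels, n_boot=50)
            assert res.auc == pytest.approx(auc_all_pairs(scores, labels), abs=1e-12)

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=40) + np.repeat([0, 1.0], 20)
        labels = np.repeat([0, 1], 20)
        res = roc_auc(scores, labels, n_boot=500, seed=1)
        assert res.ci_low <= res.auc <= res.ci_high

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestIndices:
    def test_homa_ir_printed_formula(self):
        assert homa_ir(10, 81) == pytest.approx(2.0)
        assert homa_ir(1, 405) == pytest.approx(1.0)
        assert homa_ir(5, 100) == pytest.approx(500 / 405)

    def test_homa_ir_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            homa_ir(0, 100)

    def test_insulin_unit_conversion(self):
        assert insulin_ng_to_uU(1.2) == pytest.approx(30.0)

    def test_tolerance_auc_rectangle_and_trapezoid(self):
        flat = [(0, 100), (30, 100), (60, 100), (90, 100), (120, 100)]
        assert tolerance_auc(flat) == pytest.approx(12_000)
        linear = [(0, 100), (120, 200)]
        assert tolerance_auc(linear) == pytest.approx(18_000)

    def test_tolerance_auc_incremental_subtracts_baseline(self):
        flat = [(0, 100), (120, 100)]
        assert tolerance_auc(flat, incremental=True) == pytest.approx(0.0)

    def test_tolerance_auc_matches_per_segment_sum(self):
        rng = np.random.default_rng(13)
        minutes = [0, 30, 60, 90, 120]
        glucose = rng.uniform(80, 300, size=5)
        ts = list(zip(minutes, glucose))
        by_hand = sum(
            (t2 - t1) * (g1 + g2) / 2
            for (t1, g1), (t2, g2) in zip(ts, ts[1:])
        )
        assert tolerance_auc(ts) == pytest.approx(by_hand)

    def test_unordered_minutes_rejected(self):
        with pytest.raises(ValueError):
            tolerance_auc([(30, 100), (0, 120)])

    def test_phenotype_panel_homa(self, tmp_path):
        path = tmp_path / "pheno.tsv"
        path.write_text(
            "sample\tgroup\tfasting_glucose\tfasting_insulin\tglucose_0\tglucose_30\n"
            "s1\tCtrl\t81\t10\t100\t150\n"
        )
        panels = read_phenotypes(path)
        assert panels[0].homa_ir == pytest.approx(2.0)
        assert tolerance_auc(panels[0].timeseries) == pytest.approx(30 * 125.0)
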