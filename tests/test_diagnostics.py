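import math

import numpy as np
import pytest
from scipy import stats

from lumipath import (
    ContingencyTable,
    chi_square_2x2,
    classify,
    contingency,
    diagnostic_metrics,
    rank_group_comparison,
    roc_curve,
    sample_size_auc,
    select_threshold,
    sweep_thresholds,
)
from lumipath.diagnostics import _auc_variance, _split, reference_labels
from lumipath.phantom import CohortRecord, GROUP_NEGATIVE, GROUP_POSITIVE


def rec(l_max, positive=True, sid=None):
    return CohortRecord(
        sid or f"s{l_max}", GROUP_POSITIVE if positive else GROUP_NEGATIVE, float(l_max)
    )


def make_cohort(pos_values, neg_values):
    return [rec(v, True, f"P{i}") for i, v in enumerate(pos_values)] + [
        rec(v, False, f"N{i}") for i, v in enumerate(neg_values)
    ]


# Frozen expected Table-3-style metric rows for the packaged fixture, one per
# threshold: (sens%, spec%, 1-sens%, 1-spec%, PPV%, NPV%, LR+, LR-, cred%).
TABLE3_EXPECTED = {
    1070: (66.67, 95.24, 33.33, 4.76, 94.74, 68.97, 14.00, 0.35, 79.17),
    1080: (74.07, 95.24, 25.93, 4.76, 95.24, 74.07, 15.56, 0.27, 83.33),
    1090: (81.48, 95.24, 18.52, 4.76, 95.65, 80.00, 17.11, 0.19, 87.50),
    1100: (81.48, 95.24, 18.52, 4.76, 95.65, 80.00, 17.11, 0.19, 87.50),
    1110: (81.48, 80.95, 18.52, 19.05, 84.62, 77.27, 4.28, 0.23, 81.25),
    1120: (81.48, 71.43, 18.52, 28.57, 78.57, 75.00, 2.85, 0.26, 77.08),
    1130: (81.48, 66.67, 18.52, 33.33, 75.86, 73.68, 2.44, 0.28, 75.00),
}


class TestClassify:
    def test_definition_le(self):
        records = make_cohort([1090], [1110])
        assert classify(records, 1100, "le") == [True, False]

    def test_definition_ge(self):
        records = make_cohort([1090], [1110])
        assert classify(records, 1100, "ge") == [False, True]

    def test_boundary_positive_both_directions(self):
        records = [rec(1100)]
        assert classify(records, 1100, "le") == [True]
        assert classify(records, 1100, "ge") == [True]

    def test_empty_records(self):
        with pytest.raises(ValueError, match="empty"):
            classify([], 1100, "le")

    def test_fixture_positive_total_at_1100(self, fixture_records):
        preds = classify(fixture_records, 1100, "le")
        assert sum(preds) == 23  # 22 true + 1 false positive


class TestContingency:
    def test_perfect_predictions(self):
        refs = [True] * 5 + [False] * 5
        tab = contingency(refs, refs)
        assert (tab.tp, tab.fp, tab.fn, tab.tn) == (5, 0, 0, 5)

    def test_all_positive_predictions(self):
        refs = [True] * 27 + [False] * 21
        tab = contingency([True] * 48, refs)
        assert (tab.tp, tab.fp, tab.fn, tab.tn) == (27, 21, 0, 0)

    def test_fixture_at_1100(self, fixture_records):
        tab = contingency(
            classify(fixture_records, 1100, "le"), reference_labels(fixture_records)
        )
        assert (tab.tp, tab.fp, tab.fn, tab.tn) == (22, 1, 5, 20)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            contingency([True], [True, False])

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            contingency([1], [True])

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        preds = [bool(b) for b in rng.integers(0, 2, 30)]
        refs = [bool(b) for b in rng.integers(0, 2, 30)]
        assert contingency(preds, refs).n == 30


class TestDiagnosticMetrics:
    def test_table3_row_1100(self):
        m = diagnostic_metrics(ContingencyTable(22, 1, 5, 20)).as_percent_row()
        assert m["sensitivity_pct"] == 81.48
        assert m["specificity_pct"] == 95.24
        assert m["ppv_pct"] == 95.65
        assert m["npv_pct"] == 80.00
        assert m["lr_plus"] == 17.11
        assert m["lr_minus"] == 0.19
        assert m["credibility_pct"] == 87.50

    def test_table3_row_1070(self):
        m = diagnostic_metrics(ContingencyTable(18, 1, 9, 20)).as_percent_row()
        assert m["sensitivity_pct"] == 66.67
        assert m["ppv_pct"] == 94.74
        assert m["npv_pct"] == 68.97
        assert m["lr_plus"] == 14.00
        assert m["credibility_pct"] == 79.17

    def test_perfect_test(self):
        m = diagnostic_metrics(ContingencyTable(10, 0, 0, 10))
        assert m.sensitivity == 1.0
        assert m.specificity == 1.0
        assert m.lr_plus is None  # undefined, not a number
        assert m.lr_minus == 0.0
        assert m.credibility == 1.0

    def test_undefined_ppv_when_no_positive_predictions(self):
        m = diagnostic_metrics(ContingencyTable(0, 0, 5, 5))
        assert m.ppv is None

    def test_empty_reference_margin(self):
        with pytest.raises(ValueError, match="reference-positive"):
            diagnostic_metrics(ContingencyTable(0, 5, 0, 5))
        with pytest.raises(ValueError, match="reference-negative"):
            diagnostic_metrics(ContingencyTable(5, 0, 5, 0))

    def test_complement_identities(self):
        m = diagnostic_metrics(ContingencyTable(22, 1, 5, 20))
        assert m.sensitivity + m.one_minus_sensitivity == pytest.approx(1.0)
        assert m.specificity + m.one_minus_specificity == pytest.approx(1.0)
        assert m.lr_plus == pytest.approx(m.sensitivity / (1 - m.specificity))
        assert m.lr_minus == pytest.approx((1 - m.sensitivity) / m.specificity)


class TestSweep:
    def test_fixture_reproduces_table2(self, fixture_records, fixture_thresholds):
        sweep = sweep_thresholds(fixture_records, fixture_thresholds, "le")
        expected = {
            1070: (18, 1, 9, 20), 1080: (20, 1, 7, 20), 1090: (22, 1, 5, 20),
            1100: (22, 1, 5, 20), 1110: (22, 4, 5, 17), 1120: (22, 6, 5, 15),
            1130: (22, 7, 5, 14),
        }
        for t, tab in zip(sweep.thresholds, sweep.tables):
            assert (tab.tp, tab.fp, tab.fn, tab.tn) == expected[t]

    def test_fixture_reproduces_table3(self, fixture_records, fixture_thresholds):
        sweep = sweep_thresholds(fixture_records, fixture_thresholds, "le")
        keys = (
            "sensitivity_pct", "specificity_pct", "one_minus_sensitivity_pct",
            "one_minus_specificity_pct", "ppv_pct", "npv_pct", "lr_plus",
            "lr_minus", "credibility_pct",
        )
        for t, m in zip(sweep.thresholds, sweep.metrics):
            row = m.as_percent_row()
            assert tuple(row[k] for k in keys) == TABLE3_EXPECTED[t]

    def test_separable_cohort(self):
        records = make_cohort([1000] * 8, [1200] * 6)
        sweep = sweep_thresholds(records, [1100.0], "le")
        tab = sweep.tables[0]
        assert (tab.tp, tab.fp, tab.fn, tab.tn) == (8, 0, 0, 6)

    def test_single_record_errors(self):
        with pytest.raises(ValueError):
            sweep_thresholds([rec(1000)], [1100.0], "le")

    def test_empty_grid(self, fixture_records):
        with pytest.raises(ValueError, match="grid"):
            sweep_thresholds(fixture_records, [], "le")

    def test_monotone_le_on_fixture(self, fixture_records, fixture_thresholds):
        sweep = sweep_thresholds(fixture_records, fixture_thresholds, "le")
        assert sweep.monotone()
        assert sweep.layout_monotone()

    def test_direction_inconsistency_documented(self, fixture_records, fixture_thresholds):
        # regression-documents the direction inconsistency: the published
        # assignment counts (positives non-decreasing as the threshold rises)
        # can only arise under the 'le' rule.  A real 'ge' sweep is internally
        # monotone but its layout runs the opposite way, and its TP counts
        # cannot reproduce the published (18, 20, 22, 22, 22, 22, 22).
        sweep_ge = sweep_thresholds(fixture_records, fixture_thresholds, "ge")
        assert sweep_ge.monotone()  # rule-implied invariant always holds
        assert not sweep_ge.layout_monotone()
        published_tp = (18, 20, 22, 22, 22, 22, 22)
        assert tuple(t.tp for t in sweep_ge.tables) != published_tp
        # the published TP sequence itself violates ge-monotonicity
        assert not all(a >= b for a, b in zip(published_tp, published_tp[1:]))


class TestSelectThreshold:
    def test_fixture_selects_1100_tied_with_1090(self, fixture_records, fixture_thresholds):
        sweep = sweep_thresholds(fixture_records, fixture_thresholds, "le")
        selected, rationale = select_threshold(sweep)
        assert selected == 1100
        assert rationale["tied_thresholds"] == [1090, 1100]

    def test_separable_gives_j_one(self):
        records = make_cohort([1000] * 5, [1200] * 5)
        sweep = sweep_thresholds(records, [1100.0], "le")
        selected, rationale = select_threshold(sweep)
        assert selected == 1100.0
        assert rationale["youden_j"] == pytest.approx(1.0)

    def test_single_threshold(self, fixture_records):
        sweep = sweep_thresholds(fixture_records, [1080.0], "le")
        assert select_threshold(sweep)[0] == 1080.0


class TestChiSquare:
    def test_published_value(self):
        res = chi_square_2x2(ContingencyTable(22, 1, 5, 20))
        assert round(res.chi2, 2) == 27.86
        assert round(res.cramers_v, 2) == 0.76
        assert res.p_value < 0.001
        assert res.df == 1
        assert res.p_display() == "< 0.001"

    def test_independence_gives_zero(self):
        res = chi_square_2x2(ContingencyTable(10, 10, 10, 10))
        assert res.chi2 == pytest.approx(0.0)
        assert res.cramers_v == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tp, fp, fn, tn = (int(v) for v in rng.integers(1, 40, 4))
        res = chi_square_2x2(ContingencyTable(tp, fp, fn, tn))
        # brute-force sum over the four cells
        obs = [[tp, fp], [fn, tn]]
        n = tp + fp + fn + tn
        rows = [tp + fp, fn + tn]
        cols = [tp + fn, fp + tn]
        chi2 = sum(
            (obs[i][j] - rows[i] * cols[j] / n) ** 2 / (rows[i] * cols[j] / n)
            for i in range(2)
            for j in range(2)
        )
        assert res.chi2 == pytest.approx(chi2)
        assert res.cramers_v == pytest.approx(math.sqrt(chi2 / n))
        assert res.p_value == pytest.approx(float(stats.chi2.sf(chi2, 1)))

    def test_yates_correction_differs_and_is_smaller(self):
        plain = chi_square_2x2(ContingencyTable(22, 1, 5, 20))
        corrected = chi_square_2x2(ContingencyTable(22, 1, 5, 20), correction=True)
        assert corrected.chi2 < plain.chi2
        assert round(corrected.chi2, 2) != 27.86

    def test_row_column_permutation_invariance(self):
        a = chi_square_2x2(ContingencyTable(22, 1, 5, 20))
        # swap rows and columns simultaneously: tp<->tn, fp<->fn
        b = chi_square_2x2(ContingencyTable(20, 5, 1, 22))
        assert a.chi2 == pytest.approx(b.chi2)
        assert a.cramers_v == pytest.approx(b.cramers_v)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(ContingencyTable(5, 5, 0, 0))


class TestROC:
    def test_separable_auc_one(self):
        records = make_cohort([1000, 1010, 1020], [1200, 1210])
        assert roc_curve(records, "le").auc == pytest.approx(1.0)

    def test_all_equal_auc_half(self):
        records = make_cohort([1100] * 4, [1100] * 3)
        assert roc_curve(records, "le").auc == pytest.approx(0.5)

    def test_sentinels_and_monotonicity(self, fixture_records):
        roc = roc_curve(fixture_records, "le")
        assert roc.points[0] == (0.0, 0.0)
        assert roc.points[-1] == (1.0, 1.0)
        xs = [p[0] for p in roc.points]
        ys = [p[1] for p in roc.points]
        assert xs == sorted(xs)
        assert ys == sorted(ys)
        assert 0.0 <= roc.auc <= 1.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            roc_curve([rec(1000, True)], "le")

    @pytest.mark.parametrize("seed", range(25))
    @pytest.mark.parametrize("direction", ["le", "ge"])
    def test_mann_whitney_identity(self, seed, direction):
        # trapezoidal AUC == (concordant pairs + 0.5*ties) / (n_pos*n_neg)
        rng = np.random.default_rng(seed)
        n_pos, n_neg = rng.integers(2, 15, 2)
        pos = rng.integers(900, 1300, n_pos).astype(float)
        neg = rng.integers(900, 1300, n_neg).astype(float)
        records = make_cohort(pos, neg)
        auc = roc_curve(records, direction).auc
        concordant = ties = 0
        for p in pos:
            for q in neg:
                # 'le' ranks positives low; 'ge' ranks positives high
                better = p < q if direction == "le" else p > q
                if better:
                    concordant += 1
                elif p == q:
                    ties += 1
        expected = (concordant + 0.5 * ties) / (len(pos) * len(neg))
        assert auc == pytest.approx(expected, abs=1e-12)


class TestRankGroupComparison:
    def test_identical_groups_zero(self):
        records = make_cohort([1100] * 6, [1100] * 5)
        z, p, r = rank_group_comparison(records)
        assert z == 0.0
        assert r == 0.0
        assert p == pytest.approx(1.0)

    def test_fully_separated_brute_force_oracle(self):
        pos = list(range(1000, 1027))  # 27 values, all below
        neg = list(range(2000, 2021))  # 21 values, all above
        records = make_cohort(pos, neg)
        z, p, r = rank_group_comparison(records)
        # brute-force: rank by sorting, U1 = rank-sum(pos) - n1(n1+1)/2 = 0
        n1, n2 = 27, 21
        n = n1 + n2
        u1 = 0.0
        mu = n1 * n2 / 2.0
        var = n1 * n2 * (n + 1) / 12.0
        z_expected = (u1 - mu) / math.sqrt(var)
        assert z == pytest.approx(z_expected)
        assert r == pytest.approx(z_expected / math.sqrt(n))
        assert p < 1e-8

    def test_effect_size_arithmetic(self):
        # the implemented effect size at Z=4.17, n=48 is 0.60 to 2 dp
        assert round(4.17 / math.sqrt(48), 2) == 0.60

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(4)
        records = make_cohort(rng.normal(1090, 30, 27), rng.normal(1150, 25, 21))
        z, p, _ = rank_group_comparison(records)
        ref = stats.mannwhitneyu(
            [r.l_max for r in records if r.is_positive],
            [r.l_max for r in records if not r.is_positive],
            alternative="two-sided",
            method="asymptotic",
            use_continuity=False,
        )
        assert p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_group_comparison([rec(1000, True)])


class TestSampleSizeAuc:
    def test_degenerate_errors_give_minimal_n(self):
        # z-quantiles are 0, so the first n admitting a valid ratio split wins
        assert sample_size_auc(0.5, 0.5, 0.7, 0.8) == 3

    def test_monotone_in_auc(self):
        ns = [sample_size_auc(0.01, 0.01, 0.7, a) for a in (0.7, 0.8, 0.9, 0.95)]
        assert ns == sorted(ns, reverse=True)
        assert all(isinstance(n, int) for n in ns)

    @pytest.mark.parametrize("alpha,beta,ratio,auc", [
        (0.05, 0.2, 1.0, 0.75),
        (0.01, 0.01, 0.7, 0.8),
        (0.05, 0.1, 2.0, 0.7),
    ])
    def test_minimality_against_variance_formula(self, alpha, beta, ratio, auc):
        n = sample_size_auc(alpha, beta, ratio, auc)
        z_a = float(stats.norm.isf(alpha))
        z_b = float(stats.norm.isf(beta))

        def satisfied(n_total):
            n_pos, n_neg = _split(n_total, ratio)
            if n_pos < 1 or n_neg < 1:
                return False
            sd0 = math.sqrt(_auc_variance(0.5, n_pos, n_neg))
            sd1 = math.sqrt(_auc_variance(auc, n_pos, n_neg))
            return z_a * sd0 + z_b * sd1 <= auc - 0.5

        assert satisfied(n)
        assert not satisfied(n - 1)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sample_size_auc(0.0, 0.1, 0.7, 0.8)
        with pytest.raises(ValueError):
            sample_size_auc(0.05, 0.1, -1.0, 0.8)
        with pytest.raises(ValueError):
            sample_size_auc(0.05, 0.1, 0.7, 0.5)
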