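"""Cohort comparison: difference curves, range coverage, severity groups."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tbvtools import (
    DataError,
    Sex,
    StatisticsError,
    compare_severity_groups,
    difference_curve,
    range_coverage,
    summarize_formula,
)
from tbvtools.comparison import (
    best_performing,
    group_comparison_from_values,
)
from tbvtools.estimators import EstimateSet, FormulaId, TbvEstimate, WeightBasis

LB = (FormulaId.LEMMENS_BERNSTEIN, WeightBasis.ABW)
G_ABW = (FormulaId.GILCHER_60, WeightBasis.ABW)
G_AIBW = (FormulaId.GILCHER_60, WeightBasis.AIBW)


def make_set(pid, bmi, tbvs, sex=Sex.MALE):
    """Estimate set from a {key: tbv} mapping, bypassing the formulas."""
    est = EstimateSet(patient_id=pid, sex=sex, bmi=bmi)
    for (fid, basis), tbv in tbvs.items():
        est.add(TbvEstimate(formula_id=fid, weight_basis=basis,
                            weight_used_kg=float("nan"), tbv_mL=tbv))
    return est


class TestDifferenceCurve:
    def test_worked_example_pair_is_significant(self):
        est = make_set("HYP", 40.09, {LB: 6222.2, G_ABW: 4485.8})
        (pt,) = difference_curve([est], LB, G_ABW)
        assert pt.delta_mL == pytest.approx(1736.4)
        assert pt.significant

    def test_self_difference_is_zero_everywhere(self, small_estimate_sets):
        pts = difference_curve(small_estimate_sets, LB, LB)
        assert all(p.delta_mL == 0 and not p.significant for p in pts)

    @pytest.mark.parametrize("delta, expect", [(500.0, True), (-500.0, True),
                                               (499.9, False)])
    def test_threshold_is_inclusive(self, delta, expect):
        est = make_set("P", 33.0, {LB: 5000.0 + delta, G_ABW: 5000.0})
        (pt,) = difference_curve([est], LB, G_ABW)
        assert pt.significant is expect

    @given(
        deltas=st.lists(st.floats(min_value=-3000, max_value=3000),
                        min_size=1, max_size=12),
    )
    def test_antisymmetry_under_operand_swap(self, deltas):
        sets = [
            make_set(f"P{i}", 30.0 + i, {LB: 5000.0 + d, G_ABW: 5000.0})
            for i, d in enumerate(deltas)
        ]
        fwd = difference_curve(sets, LB, G_ABW)
        rev = difference_curve(sets, G_ABW, LB)
        for a, b in zip(fwd, rev):
            assert a.patient_id == b.patient_id
            assert a.delta_mL == -b.delta_mL
            assert a.significant == b.significant

    def test_sorted_by_bmi_then_id(self):
        sets = [make_set(pid, bmi, {LB: 5000.0, G_ABW: 4800.0})
                for pid, bmi in [("B", 35.0), ("A", 35.0), ("C", 31.0)]]
        pts = difference_curve(sets, LB, G_ABW)
        assert [p.patient_id for p in pts] == ["C", "A", "B"]

    def test_missing_formula_names_patient(self):
        sets = [make_set("OK", 32.0, {LB: 5000.0, G_ABW: 4800.0}),
                make_set("BAD", 33.0, {LB: 5000.0})]
        with pytest.raises(DataError, match="BAD"):
            difference_curve(sets, LB, G_ABW)


class TestRangeCoverage:
    def test_containment_examples(self):
        one = make_set("M1", 40.0, {LB: 5113.0})
        cov = range_coverage([one], LB, Sex.MALE, (4000, 7000))
        assert (cov.n_within, cov.n_under, cov.n_over) == (1, 0, 0)

        triple = [
            make_set(f"F{i}", 32.0, {LB: v}, sex=Sex.FEMALE)
            for i, v in enumerate([3400.0, 3500.0, 6600.0])
        ]
        cov = range_coverage(triple, LB, Sex.FEMALE, (3500, 6500))
        assert (cov.n_under, cov.n_within, cov.n_over) == (1, 1, 1)

    def test_bounds_inclusive(self):
        edges = [make_set(f"M{i}", 36.0, {LB: v})
                 for i, v in enumerate([4000.0, 7000.0])]
        cov = range_coverage(edges, LB, Sex.MALE)
        assert cov.n_within == 2

    def test_empty_cohort(self):
        cov = range_coverage([], LB, Sex.FEMALE)
        assert cov.n_total == 0
        assert math.isnan(cov.fraction_within)

    def test_wrong_sex_rejected(self):
        est = make_set("F1", 32.0, {LB: 5000.0}, sex=Sex.FEMALE)
        with pytest.raises(DataError, match="F1"):
            range_coverage([est], LB, Sex.MALE)

    @given(values=st.lists(st.floats(min_value=2000, max_value=10000),
                           min_size=1, max_size=30),
           split=st.integers(min_value=0, max_value=30))
    def test_counts_additive_over_partitions(self, values, split):
        sets = [make_set(f"M{i}", 33.0, {LB: v}) for i, v in enumerate(values)]
        split = min(split, len(sets))
        whole = range_coverage(sets, LB, Sex.MALE)
        left = range_coverage(sets[:split], LB, Sex.MALE)
        right = range_coverage(sets[split:], LB, Sex.MALE)
        assert whole.n_within == left.n_within + right.n_within
        assert whole.n_under == left.n_under + right.n_under
        assert whole.n_over == left.n_over + right.n_over
        assert whole.n_total == len(values)

    def test_best_performing_is_highest_fraction(self):
        sets = [make_set(f"M{i}", 36.0, {LB: 5000.0 + 3000 * i,
                                         G_ABW: 5000.0})
                for i in range(4)]
        covs = [range_coverage(sets, key, Sex.MALE) for key in (LB, G_ABW)]
        assert best_performing(covs).formula == G_ABW


class TestSummaries:
    def test_examples(self):
        assert summarize_formula([make_set("A", 32.0, {LB: 4000.0})], LB) == (
            4000.0, 4000.0, 4000.0)
        four = [make_set(f"P{i}", 32.0, {LB: v})
                for i, v in enumerate([3000.0, 4000.0, 5000.0, 6000.0])]
        assert summarize_formula(four, LB)[1] == 4500.0  # even-n midpoint
        three = [make_set(f"P{i}", 32.0, {LB: v})
                 for i, v in enumerate([2922.0, 3759.0, 4736.0])]
        assert summarize_formula(three, LB) == (2922.0, 3759.0, 4736.0)

    def test_empty_is_an_error(self):
        with pytest.raises(DataError):
            summarize_formula([], LB)


class TestSeverityComparison:
    def test_identical_groups_null_result(self):
        g = group_comparison_from_values([4000, 4100, 3900], [4000, 4100, 3900])
        assert g.mean_difference_mL == 0
        assert g.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert g.p_value == pytest.approx(1.0)
        assert not g.functionally_significant

    def test_welch_t_against_closed_form(self):
        """4+4 shifted groups with equal spread: t from the hand formula."""
        a = [5000.0, 5200.0, 5100.0, 4900.0]
        b = [5600.0, 5800.0, 5700.0, 5500.0]
        g = group_comparison_from_values(a, b)
        var = 50000.0 / 3.0  # both groups: sample variance of +-50, +-150
        t_hand = 600.0 / math.sqrt(2 * var / 4)
        assert g.mean_difference_mL == pytest.approx(600.0)
        assert g.t_statistic == pytest.approx(t_hand, rel=1e-12)
        # equal sizes and variances: Welch df reduces to n1+n2-2 = 6
        assert g.p_value == pytest.approx(2 * stats.t.sf(t_hand, df=6),
                                          rel=1e-9)
        assert g.functionally_significant

    def test_small_class_is_an_error(self):
        with pytest.raises(StatisticsError):
            group_comparison_from_values([4000.0], [5000.0, 5100.0])

    def test_from_estimate_sets_classifies_by_bmi(self):
        sets = (
            [make_set(f"N{i}", 31.0 + i, {LB: 4900.0 + 50 * i})
             for i in range(3)]
            + [make_set(f"S{i}", 36.0 + i, {LB: 5600.0 + 50 * i})
               for i in range(3)]
            + [make_set("LEAN", 28.0, {LB: 4000.0})]  # excluded: non-obese
        )
        g = compare_severity_groups(sets, LB, sex=Sex.MALE)
        assert (g.n_nonsevere, g.n_severe) == (3, 3)
        assert g.mean_difference_mL == pytest.approx(700.0)
        assert g.functionally_significant

    def test_pooled_option_matches_pooled_ttest(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(5000, 400, 12), rng.normal(5300, 500, 9)
        g = group_comparison_from_values(a, b, equal_var=True)
        ref = stats.ttest_ind(b, a, equal_var=True)
        assert g.t_statistic == pytest.approx(float(ref.statistic))
        assert g.p_value == pytest.approx(float(ref.pvalue))


class TestCalibrationAndPower:
    def test_type_i_error_near_nominal(self):
        """Null rejection rate at alpha=0.05 stays within 0.05 +- 0.02."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            pooled = rng.normal(5000.0, 400.0, size=60)
            g = group_comparison_from_values(pooled[:30], pooled[30:])
            rejections += g.p_value < 0.05
        assert abs(rejections / n_rep - 0.05) <= 0.02

    def test_power_and_recovery_of_600mL_shift(self):
        """A 600 mL class shift (sd 400, n=30/30) is detected and recovered."""
        rng = np.random.default_rng(99)
        n_rep = 200
        diffs, hits = [], 0
        for _ in range(n_rep):
            a = rng.normal(5000.0, 400.0, size=30)
            b = rng.normal(5600.0, 400.0, size=30)
            g = group_comparison_from_values(a, b)
            diffs.append(g.mean_difference_mL)
            hits += g.p_value < 0.05
        assert hits / n_rep > 0.9
        assert abs(float(np.mean(diffs)) - 600.0) <= 100.0
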