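import math

import hypothesis.strategies as st
import pytest
from hypothesis import assume, given

from yearscxr import (
    TwoByTwo,
    bootstrap_ci,
    build_two_by_two,
    likelihood_ratio_negative,
    likelihood_ratio_positive,
    odds_ratio,
    posttest_probability,
)
from yearscxr.stats import format_or, format_point, format_ratio

cells = st.integers(0, 500)
tables = st.builds(TwoByTwo, cells, cells, cells, cells)


class TestBuildTwoByTwo:
    def test_abnormal_versus_pe_from_reference_cohort(self, reference_records):
        t = build_two_by_two(reference_records, "abnormal", "pe")
        assert t.cells() == (77, 137, 327, 932)

    def test_consolidation_versus_pe(self, reference_records):
        t = build_two_by_two(reference_records, "consolidation", "pe")
        assert t.cells() == (49, 165, 157, 1102)

    def test_empty_cohort_gives_zero_cells(self):
        assert build_two_by_two([], "abnormal", "pe").cells() == (0, 0, 0, 0)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 0, 0, 0)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "t,printed",
        [
            (TwoByTwo(77, 137, 327, 932), "1.60 (1.18–2.18)"),
            (TwoByTwo(49, 165, 157, 1102), "2.08 (1.45–2.99)"),
            (TwoByTwo(604, 106, 465, 298), "3.65 (2.84–4.70)"),
        ],
    )
    def test_reference_values(self, t, printed):
        assert format_or(odds_ratio(t)) == printed

    @given(st.integers(1, 100), st.integers(1, 100))
    def test_balanced_table_gives_unit_odds_ratio(self, x, y):
        # a*d == b*c forces OR == 1
        est = odds_ratio(TwoByTwo(x, y, x, y))
        assert est.point == pytest.approx(1.0)

    @given(tables)
    def test_invariant_under_transpose_symmetry(self, t):
        assume(not t.has_zero_cell)
        swapped = TwoByTwo(t.d, t.c, t.b, t.a)
        assert odds_ratio(swapped).point == pytest.approx(odds_ratio(t).point)

    def test_zero_numerator_gives_zero_without_interval(self):
        est = odds_ratio(TwoByTwo(0, 10, 5, 20))
        assert est.point == 0.0 and est.ci_low is None and est.zero_cell

    def test_zero_denominator_is_undefined_with_flag(self):
        est = odds_ratio(TwoByTwo(5, 0, 3, 20))
        assert math.isnan(est.point) and est.zero_cell

    @given(tables)
    def test_matches_statsmodels_woolf_interval(self, t):
        """Independent cross-check of the log-method interval."""
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        assume(not t.has_zero_cell)
        table = sm_ct.Table2x2(
            [[t.a, t.c], [t.b, t.d]], shift_zeros=False
        )
        est = odds_ratio(t)
        assert est.point == pytest.approx(table.oddsratio)
        low, high = table.oddsratio_confint(0.05)
        # statsmodels uses the exact normal quantile; we fix z = 1.96
        assert est.ci_low == pytest.approx(low, rel=1e-3)
        assert est.ci_high == pytest.approx(high, rel=1e-3)


class TestLikelihoodRatios:
    @pytest.mark.parametrize(
        "t,printed",
        [
            (TwoByTwo(49, 165, 157, 1102), "1.8 (1.4–2.4)"),
            (TwoByTwo(137, 77, 932, 327), "0.86 (0.78–0.96)"),
            (TwoByTwo(0, 214, 2, 1257), "0.00"),
        ],
    )
    def test_positive_reference_values(self, t, printed):
        assert format_ratio(likelihood_ratio_positive(t)) == printed

    @pytest.mark.parametrize(
        "t,printed",
        [
            (TwoByTwo(137, 77, 932, 327), "1.4 (1.1–1.7)"),
            (TwoByTwo(49, 165, 157, 1102), "0.88 (0.82–0.95)"),
        ],
    )
    def test_negative_reference_values(self, t, printed):
        assert format_ratio(likelihood_ratio_negative(t)) == printed

    @given(st.integers(1, 300), st.integers(1, 300))
    def test_finding_present_everywhere_gives_unit_positive_lr(self, n1, n2):
        assert likelihood_ratio_positive(
            TwoByTwo(n1, 0, n2, 0)
        ).point == pytest.approx(1.0)

    @given(st.integers(1, 300), st.integers(1, 300))
    def test_finding_absent_everywhere_gives_unit_negative_lr(self, n1, n2):
        assert likelihood_ratio_negative(
            TwoByTwo(0, n1, 0, n2)
        ).point == pytest.approx(1.0)

    def test_denominator_zero_is_undefined(self):
        est = likelihood_ratio_positive(TwoByTwo(5, 10, 0, 20))
        assert math.isnan(est.point) and est.zero_cell

    def test_empty_outcome_group_rejected(self):
        with pytest.raises(ValueError, match="outcome group"):
            likelihood_ratio_positive(TwoByTwo(0, 0, 5, 5))

    @given(tables)
    def test_sensitivity_identity(self, t):
        """LR+ · (1 − specificity) recovers sensitivity exactly."""
        assume(t.a > 0 and t.c > 0 and t.n_pos > 0 and t.n_neg > 0)
        est = likelihood_ratio_positive(t)
        sens = t.a / t.n_pos
        assert est.point * (t.c / t.n_neg) == pytest.approx(sens, rel=1e-12)

    def test_zero_cell_elsewhere_keeps_uncorrected_point(self):
        # a = 0 leaves LR- defined; its point must not be shifted by the
        # interval's Haldane correction
        t = TwoByTwo(0, 214, 2, 1257)
        est = likelihood_ratio_negative(t)
        assert est.point == pytest.approx((214 / 214) / (1257 / 1259))
        assert est.ci_low < 1 < est.ci_high


class TestPosttestProbability:
    @pytest.mark.parametrize(
        "pretest,lr,method,expected",
        [
            (0.28, 1.1, "multiplicative", 0.308),
            (0.28, 0.89, "multiplicative", 0.2492),
            (0.28, 1.1, "bayes_odds", 0.29961089494163424),
        ],
    )
    def test_worked_examples(self, pretest, lr, method, expected):
        assert posttest_probability(pretest, lr, method) == pytest.approx(expected)

    @given(
        st.floats(0, 1, allow_nan=False),
        st.sampled_from(["multiplicative", "bayes_odds"]),
    )
    def test_unit_lr_changes_nothing(self, p, method):
        assert posttest_probability(p, 1.0, method) == pytest.approx(p)

    def test_certain_pretest_stays_certain(self):
        assert posttest_probability(1.0, 0.5, "bayes_odds") == 1.0

    @given(
        st.floats(0.001, 0.999),
        st.floats(0.001, 0.999),
        st.floats(0.01, 50),
        st.floats(0.01, 50),
    )
    def test_bayes_update_is_monotone(self, p1, p2, lr1, lr2):
        p_lo, p_hi = sorted((p1, p2))
        lr_lo, lr_hi = sorted((lr1, lr2))
        assert posttest_probability(
            p_hi, lr_hi, "bayes_odds"
        ) >= posttest_probability(p_lo, lr_hi, "bayes_odds") >= posttest_probability(
            p_lo, lr_lo, "bayes_odds"
        )

    @given(st.floats(0.1, 10))
    def test_multiplicative_matches_bayes_at_small_pretest(self, lr):
        p = 1e-5
        mult = posttest_probability(p, lr, "multiplicative")
        bayes = posttest_probability(p, lr, "bayes_odds")
        assert mult == pytest.approx(bayes, rel=1e-3)

    def test_probability_capped_at_one(self):
        assert posttest_probability(0.9, 5.0, "multiplicative") == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            posttest_probability(1.5, 1.0)
        with pytest.raises(ValueError):
            posttest_probability(0.5, -1.0)
        with pytest.raises(ValueError):
            posttest_probability(0.5, 1.0, "nonsense")


class TestBootstrap:
    def test_brackets_the_point_estimate(self):
        t = TwoByTwo(49, 165, 157, 1102)
        low, high = bootstrap_ci(t, "lr_positive", n_resamples=2000, seed=3)
        assert low < likelihood_ratio_positive(t).point < high

    def test_requires_non_empty_groups(self):
        with pytest.raises(ValueError):
            bootstrap_ci(TwoByTwo(0, 0, 5, 5), "lr_positive")


@pytest.mark.parametrize(
    "value,printed",
    [
        (float("nan"), "n.a."),
        (0.0, "0.00"),
        (0.864, "0.86"),
        (0.9986, "1.0"),
        (1.0016, "1.0"),
        (1.0495, "1.0"),
        (1.836, "1.8"),
        (3.652, "3.7"),
        (12.4, "12"),
    ],
)
def test_report_precision_formatting(value, printed):
    assert format_point(value) == printed
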