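"""Contingency engine: expected counts, test selection, chi-square, Fisher,
Woolf and logistic odds ratios."""

import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from tscgp.stats import (DegenerateTableError, Table2x2, chi_square_test,
                         expected_counts, fisher_exact_test, logistic_crude_or,
                         odds_ratio_woolf, run_selected_test, select_test)

tables_strategy = st.tuples(*[st.integers(0, 30)] * 4).filter(lambda t: sum(t) > 0)


def fisher_oracle(a, b, c, d):
    """Independent enumeration over all tables with the observed margins,
    via exact Fraction probabilities of the full four-cell table."""
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    N = r1 + r2
    f = math.factorial
    probs = []
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        aa, bb, cc, dd = k, r1 - k, c1 - k, r2 - c1 + k
        probs.append(Fraction(f(r1) * f(r2) * f(c1) * f(c2),
                              f(N) * f(aa) * f(bb) * f(cc) * f(dd)))
    if len(probs) == 1:
        return 1.0
    obs = probs[a - max(0, c1 - r2)]
    cutoff = obs * Fraction(10 ** 9 + 100, 10 ** 9)  # the documented tie rule
    return float(min(Fraction(1), sum(p for p in probs if p <= cutoff)))


class TestExpectedCountsAndSelection:
    def test_expected_counts_sex_table(self):
        e = expected_counts(Table2x2(47, 38, 21, 42))
        assert e.sum() == pytest.approx(148)
        assert e.min() == pytest.approx(63 * 68 / 148)

    def test_expected_counts_trivial(self):
        assert np.allclose(expected_counts(Table2x2(1, 1, 1, 1)), 1.0)
        assert np.allclose(expected_counts(Table2x2(0, 0, 5, 5))[0], 0.0)

    @pytest.mark.parametrize("cells, method", [
        ((47, 38, 21, 42), "chi_square"),         # large table, all expected > 5
        ((1, 95, 4, 96), "chi_square_yates"),     # min expected ~2.45
        ((2, 3, 4, 5), "fisher_exact"),           # N = 14 < 40
        ((0, 0, 5, 5), "fisher_exact"),           # expected counts of 0
    ])
    def test_selection_rule(self, cells, method):
        assert select_test(Table2x2(*cells)) == method

    def test_fisher_precedence_over_continuity(self):
        # min expected < 1 forces Fisher even though N >= 40
        t = Table2x2(1, 0, 60, 59)
        assert expected_counts(t).min() < 1 and t.n >= 40
        assert select_test(t) == "fisher_exact"


class TestChiSquare:
    def test_closed_form_statistic_and_p(self):
        r = chi_square_test(Table2x2(47, 38, 21, 42))
        assert r.statistic == pytest.approx(7.0261, abs=1e-3)
        assert round(r.p_value, 3) == 0.008

    def test_yates_floor_gives_p_one(self):
        r = chi_square_test(Table2x2(3, 93, 3, 97), yates=True)
        assert r.statistic == 0 and r.p_value == 1.0

    def test_yates_example(self):
        assert round(chi_square_test(Table2x2(1, 95, 4, 96), yates=True).p_value, 2) == 0.39

    def test_zero_margin_raises(self):
        with pytest.raises(DegenerateTableError):
            chi_square_test(Table2x2(0, 0, 5, 5))

    def test_against_scipy(self):
        for cells in [(47, 38, 21, 42), (15, 5, 81, 95), (6, 12, 16, 20)]:
            t = Table2x2(*cells)
            for yates in (False, True):
                stat, p, _, _ = sps.chi2_contingency(t.as_array(), correction=yates)
                r = chi_square_test(t, yates=yates)
                assert r.statistic == pytest.approx(stat)
                assert r.p_value == pytest.approx(p)

    @given(tables_strategy)
    @settings(max_examples=200, deadline=None)
    def test_yates_never_exceeds_uncorrected(self, cells):
        t = Table2x2(*cells)
        if 0 in t.row_totals or 0 in t.col_totals:
            return
        plain, corr = chi_square_test(t), chi_square_test(t, yates=True)
        assert corr.statistic <= plain.statistic + 1e-12
        assert 0 <= plain.p_value <= 1 and corr.p_value >= plain.p_value - 1e-12


class TestFisher:
    def test_hand_enumerated_examples(self):
        assert fisher_exact_test(Table2x2(1, 0, 0, 1)).p_value == 1.0
        assert fisher_exact_test(Table2x2(5, 0, 0, 5)).p_value == pytest.approx(2 / 252)
        assert fisher_exact_test(Table2x2(0, 5, 5, 0)).p_value == pytest.approx(2 / 252)

    def test_degenerate_margins_give_p_one(self):
        assert fisher_exact_test(Table2x2(0, 0, 3, 4)).p_value == 1.0
        assert fisher_exact_test(Table2x2(2, 0, 3, 0)).p_value == 1.0

    @given(tables_strategy)
    @settings(max_examples=400, deadline=None)
    def test_matches_enumeration_oracle(self, cells):
        assert fisher_exact_test(Table2x2(*cells)).p_value == fisher_oracle(*cells)

    @given(tables_strategy)
    @settings(max_examples=150, deadline=None)
    def test_matches_scipy(self, cells):
        p = fisher_exact_test(Table2x2(*cells)).p_value
        assert p == pytest.approx(sps.fisher_exact(
            [[cells[0], cells[1]], [cells[2], cells[3]]]).pvalue, rel=1e-9)


class TestWoolf:
    def test_symmetric_trivial_table(self):
        r = odds_ratio_woolf(Table2x2(1, 1, 1, 1))
        assert r.or_point == 1.0
        assert r.ci_low == pytest.approx(1 / r.ci_high)

    def test_log_symmetry(self):
        r = odds_ratio_woolf(Table2x2(15, 5, 81, 95))
        assert math.log(r.ci_high) - math.log(r.or_point) == pytest.approx(
            math.log(r.or_point) - math.log(r.ci_low))

    def test_zero_cell_undefined_unless_haldane(self):
        r = odds_ratio_woolf(Table2x2(0, 5, 5, 5))
        assert not r.defined
        h = odds_ratio_woolf(Table2x2(0, 5, 5, 5), haldane=True)
        assert h.defined and h.adjusted

    @given(tables_strategy.filter(lambda t: min(t) > 0))
    @settings(max_examples=200, deadline=None)
    def test_exposure_swap_antisymmetry(self, cells):
        t = Table2x2(*cells)
        r, rs = odds_ratio_woolf(t), odds_ratio_woolf(t.swap_exposure())
        assert rs.or_point == pytest.approx(1 / r.or_point)
        assert rs.ci_low == pytest.approx(1 / r.ci_high)
        assert rs.ci_high == pytest.approx(1 / r.ci_low)


class TestLogistic:
    def test_flat_table_gives_null_or(self):
        r = logistic_crude_or(Table2x2(2, 2, 2, 2))
        assert r.or_point == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_separation_raises(self):
        with pytest.raises(DegenerateTableError):
            logistic_crude_or(Table2x2(0, 5, 5, 5))

    @given(st.tuples(*[st.integers(1, 40)] * 4))
    @settings(max_examples=60, deadline=None)
    def test_equals_woolf_on_saturated_model(self, cells):
        t = Table2x2(*cells)
        lo = logistic_crude_or(t)
        wo = odds_ratio_woolf(t)
        assert lo.or_point == pytest.approx(wo.or_point, rel=1e-6)
        assert lo.ci_low == pytest.approx(wo.ci_low, rel=1e-6)
        assert lo.ci_high == pytest.approx(wo.ci_high, rel=1e-6)


def test_null_rejection_rate_of_selected_test():
    """Simulated 2x2 tables under independence (OR = 1): the rule-selected
    test rejects at alpha = 0.05 no more often than ~5% plus Monte-Carlo
    error (continuity-corrected and exact branches are conservative)."""
    rng = np.random.default_rng(20)
    n, reps = 200, 10_000
    tables = rng.multinomial(n, [0.25] * 4, size=reps)
    rejected = 0
    for a, b, c, d in tables:
        if run_selected_test(Table2x2(int(a), int(b), int(c), int(d))).p_value < 0.05:
            rejected += 1
    rate = rejected / reps
    assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / reps)
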