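import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrminer.apriori import Itemset
from adrminer.association import (
    ContingencyTable,
    MiningParams,
    UndefinedStatisticError,
    build_table,
    chi_square,
    comp,
    mine_rules,
    min_tev,
    reconstruct_table,
    rule_strength_rank,
    validity_check,
)
from adrminer.synthetic import generate_cohort, planted_spec
from conftest import make_db


def chi_square_expected_form(t: ContingencyTable) -> float:
    """Independent oracle: sum (O-E)^2/E over the four cells."""
    obs = (t.a, t.b, t.c, t.d)
    return sum((o - e) ** 2 / e for o, e in zip(obs, t.expected()))


cells = st.integers(min_value=1, max_value=500)


class TestChiSquare:
    def test_perfect_independence_is_zero(self):
        assert chi_square(ContingencyTable(10, 10, 10, 10)) == 0.0

    def test_matches_expected_count_form_on_reconstruction(self):
        t = ContingencyTable(1767, 1109, 4659, 8992)
        assert chi_square(t) == pytest.approx(745.572, abs=0.01)
        assert chi_square(t) == pytest.approx(chi_square_expected_form(t), rel=1e-9)

    def test_symmetric_under_simultaneous_row_col_swap(self):
        t = ContingencyTable(30, 7, 12, 51)
        swapped = ContingencyTable(51, 12, 7, 30)
        assert chi_square(t) == pytest.approx(chi_square(swapped), rel=1e-12)

    def test_zero_margin_raises(self):
        with pytest.raises(UndefinedStatisticError):
            chi_square(ContingencyTable(0, 0, 5, 5))

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_shortcut_equals_expected_count_form(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        assert chi_square(t) == pytest.approx(chi_square_expected_form(t), rel=1e-9,
                                              abs=1e-12)


class TestComp:
    def test_zero_iff_ad_equals_bc(self):
        assert comp(ContingencyTable(6, 3, 4, 2)) == 0.0

    def test_signed_root_of_chi_square(self):
        t = ContingencyTable(1767, 1109, 4659, 8992)
        assert comp(t) == pytest.approx(27.305, abs=0.001)

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_square_recovers_chi2_and_sign_follows_odds_ratio(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        v = comp(t)
        assert v * v == pytest.approx(chi_square(t), rel=1e-9, abs=1e-12)
        det = a * d - b * c
        odds_ratio = (a * d) / (b * c)
        assert np.sign(v) == np.sign(det)
        if det:
            assert (v > 0) == (odds_ratio > 1)


class TestMinTev:
    def test_paper_mode_is_chi2_critical_value(self):
        assert min_tev(0.05, "paper") == pytest.approx(3.841, abs=5e-4)

    def test_sqrt_scale_is_normal_critical_value(self):
        assert min_tev(0.05, "sqrt_scale") == pytest.approx(1.95996, abs=1e-5)

    def test_limit_alpha_to_one_is_zero(self):
        assert min_tev(1 - 1e-12, "paper") == pytest.approx(0.0, abs=1e-6)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            min_tev(0.0)


class TestValidity:
    def test_n_40_boundary_fails(self):
        assert not validity_check(ContingencyTable(10, 10, 10, 10))

    def test_large_balanced_table_valid(self):
        assert validity_check(ContingencyTable(100, 100, 100, 100))

    def test_small_expected_count_fails(self):
        # expected a-cell = 2*100/200 = 1 < 5
        assert not validity_check(ContingencyTable(1, 99, 1, 99))


class TestBuildTable:
    def test_hand_count(self):
        db = make_db({"P1": {"a"}, "P2": {"a"}, "P3": set()},
                     {"P1": {"x"}, "P3": {"x"}})
        t = build_table(db, ("a",), "x")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 0)

    def test_absent_drug_gives_empty_row(self):
        db = make_db({"P1": {"a"}}, {"P1": {"x"}})
        t = build_table(db, ("zzz",), "x")
        assert t.a == 0 and t.b == 0
        with pytest.raises(UndefinedStatisticError):
            chi_square(t)

    def test_two_drug_antecedent_needs_both(self):
        db = make_db({"P1": {"a", "b"}, "P2": {"a"}, "P3": {"b"}},
                     {"P1": {"x"}, "P2": {"x"}})
        t = build_table(db, ("a", "b"), "x")
        assert (t.a, t.b) == (1, 0)


def test_reconstruct_table_from_printed_marginals():
    t = reconstruct_table(16527, 0.174, 61.426, 6426)
    assert (t.a, t.b, t.c, t.d) == (1767, 1109, 4659, 8992)
    assert t.n == 16527


class TestMineRules:
    def test_planted_positive_and_negative_recovered(self):
        cohort = generate_cohort(planted_spec(or_positive=5.0, or_negative=0.2,
                                              seed=11))
        db = cohort.itemset_db()
        rules = mine_rules(db, MiningParams(min_sup=0.01, min_cof=1.0,
                                            threshold_mode="paper"))
        by_pair = {(r.antecedent, r.consequent): r for r in rules}
        pos = by_pair[(("drug00",), "ae00")]
        neg = by_pair[(("drug01",), "ae01")]
        assert pos.direction == "positive" and neg.direction == "negative"
        assert pos.valid and neg.valid

    def test_rule_invariants_hold_on_mined_rules(self):
        cohort = generate_cohort(planted_spec(seed=3))
        rules = mine_rules(cohort.itemset_db(), MiningParams(min_sup=0.01))
        assert rules
        thr = min_tev(0.05, "paper")
        for r in rules:
            assert r.comp**2 == pytest.approx(r.chi2, rel=1e-9)
            t = r.table
            assert np.sign(r.comp) == np.sign(t.a * t.d - t.b * t.c)
            assert r.confidence == pytest.approx(100 * t.a / (t.a + t.b), rel=1e-12)
            assert abs(r.comp) > thr
            assert (r.direction == "positive") == (r.comp > thr)

    def test_screens_shrink_rule_set_monotonically(self):
        cohort = generate_cohort(planted_spec(seed=5))
        db = cohort.itemset_db()
        base = mine_rules(db, MiningParams(min_sup=0.01, min_cof=5.0, alpha=0.05))
        higher_cof = mine_rules(db, MiningParams(min_sup=0.01, min_cof=20.0,
                                                 alpha=0.05))
        higher_tev = mine_rules(db, MiningParams(min_sup=0.01, min_cof=5.0,
                                                 alpha=0.001))
        key = lambda rules: {(r.antecedent, r.consequent) for r in rules}
        assert key(higher_cof) <= key(base)
        assert key(higher_tev) <= key(base)

    def test_support_definitions(self):
        cohort = generate_cohort(planted_spec(seed=7))
        db = cohort.itemset_db()
        ant = mine_rules(db, MiningParams(min_sup=0.01, support_def="antecedent"))
        joint = {(r.antecedent, r.consequent): r
                 for r in mine_rules(db, MiningParams(min_sup=0.01,
                                                      support_def="joint"))}
        for r in ant:
            j = joint[(r.antecedent, r.consequent)]
            assert j.support == pytest.approx(r.table.a / r.table.n)
            assert r.support >= j.support  # antecedent support dominates joint

    def test_bh_correction_only_removes_rules(self):
        cohort = generate_cohort(planted_spec(seed=9))
        db = cohort.itemset_db()
        plain = mine_rules(db, MiningParams(min_sup=0.01))
        bh = mine_rules(db, MiningParams(min_sup=0.01, bh_correct=True))
        key = lambda rules: {(r.antecedent, r.consequent) for r in rules}
        assert key(bh) <= key(plain)


def test_rule_strength_rank_orders_by_absolute_comp():
    def rule(compv, ant=("a",)):
        from adrminer.association import AssociationRule

        return AssociationRule(ant, "x", ContingencyTable(1, 1, 1, 1), 0.1,
                               50.0, compv**2, compv, "none", True)

    ranked = rule_strength_rank([rule(5.0), rule(-7.0), rule(2.0)])
    assert [r.comp for r in ranked] == [-7.0, 5.0, 2.0]
    tied = rule_strength_rank([rule(3.0, ("b",)), rule(3.0, ("a",))])
    assert [r.antecedent for r in tied] == [("a",), ("b",)]
    assert rule_strength_rank([]) == []
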