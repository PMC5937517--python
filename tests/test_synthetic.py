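import math

import numpy as np
import pytest

from adrminer.association import AssociationRule, ContingencyTable
from adrminer.synthetic import (
    SyntheticSpec,
    evaluate_against_truth,
    generate_cohort,
    null_spec,
    planted_spec,
    write_cohort,
)


def _rule(ant, cons, direction):
    return AssociationRule(tuple(ant), cons, ContingencyTable(5, 5, 5, 5),
                           0.1, 50.0, 4.0, 2.0 if direction == "positive" else -2.0,
                           direction, True)


class TestGenerateCohort:
    def test_same_seed_reproduces_byte_identical_tables(self, tmp_path):
        a = write_cohort(generate_cohort(planted_spec(seed=5)), tmp_path / "a")
        b = write_cohort(generate_cohort(planted_spec(seed=5)), tmp_path / "b")
        for k in a:
            assert open(a[k], "rb").read() == open(b[k], "rb").read()

    def test_different_seeds_differ(self):
        a = generate_cohort(null_spec(n_patients=500, seed=1))
        b = generate_cohort(null_spec(n_patients=500, seed=2))
        assert not a.exposures.equals(b.exposures)

    def test_null_rates_recover_their_parameters(self):
        # marginal drug prevalences and AE rates recover their generative
        # values; with 30 marginals checked jointly the bound on each |z|
        # must be wider than the single-test 3 s.e. (max of 30 standard
        # normals exceeds 4 with probability ~0.2%)
        spec = null_spec(n_patients=10000, seed=13)
        cohort = generate_cohort(spec)
        n = spec.n_patients
        zs = []
        exp_counts = cohort.exposures["drug_code"].value_counts()
        for drug, p in spec.drugs:
            se = math.sqrt(p * (1 - p) / n)
            zs.append(abs(exp_counts.get(drug, 0) / n - p) / se)
        ae_counts = cohort.adverse_events["ae_term"].value_counts()
        for ae, p in spec.aes:
            se = math.sqrt(p * (1 - p) / n)
            zs.append(abs(ae_counts.get(ae, 0) / n - p) / se)
        assert max(zs) < 4.0
        assert np.mean(zs) < 1.5

    def test_planted_effect_raises_conditional_rate(self):
        cohort = generate_cohort(planted_spec(or_positive=5.0, seed=17))
        db = cohort.itemset_db()
        from adrminer.association import build_table

        t = build_table(db, ("drug00",), "ae00")
        assert t.a / (t.a + t.b) > t.c / (t.c + t.d)

    def test_planting_is_sign_faithful_across_replicates(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            cohort = generate_cohort(planted_spec(seed=seed))
            db = cohort.itemset_db()
            from adrminer.association import build_table

            t = build_table(db, ("drug00",), "ae00")
            if t.a * t.d > t.b * t.c:
                hits += 1
        assert hits >= 0.95 * reps

    def test_co_rx_boost_raises_joint_exposure(self):
        spec = planted_spec(n_patients=10000, seed=19)  # boosts drug02+drug03
        cohort = generate_cohort(spec)
        db = cohort.itemset_db()
        both = sum(1 for pid in db.patients
                   if {"drug02", "drug03"} <= db.drug_sets[pid])
        independent = 0.2 * 0.2 * spec.n_patients
        assert both > 1.5 * independent

    def test_zero_patients_gives_empty_cohort(self):
        cohort = generate_cohort(null_spec(n_patients=0))
        assert cohort.exposures.empty and cohort.adverse_events.empty
        assert cohort.truth["effects"] == []

    def test_invalid_spec_names_the_field(self):
        spec = null_spec()
        spec.effects = {("nope", "ae00"): 2.0}
        with pytest.raises(ValueError, match="effects"):
            generate_cohort(spec)
        spec2 = null_spec()
        spec2.drugs[0] = ("drug00", 1.5)
        with pytest.raises(ValueError, match="prevalence"):
            generate_cohort(spec2)


class TestEvaluateAgainstTruth:
    TRUTH = {
        "effects": [
            {"drug": "drug00", "ae_term": "ae00", "odds_ratio": 3.0},
            {"drug": "drug01", "ae_term": "ae01", "odds_ratio": 0.3},
        ]
    }

    def test_perfect_rules_score_one(self):
        rules = [_rule(["drug00"], "ae00", "positive"),
                 _rule(["drug01"], "ae01", "negative")]
        m = evaluate_against_truth(rules, self.TRUTH)
        assert m["precision"] == m["recall"] == m["sign_accuracy"] == 1.0

    def test_empty_rules_flag_undefined_precision(self):
        m = evaluate_against_truth([], self.TRUTH)
        assert m["recall"] == 0.0
        assert m["precision"] == 1.0 and m["precision_defined"] is False

    def test_wrong_sign_not_recalled(self):
        rules = [_rule(["drug00"], "ae00", "negative")]
        m = evaluate_against_truth(rules, self.TRUTH)
        assert m["recall"] == 0.0

    def test_two_drug_rule_policy(self):
        rules = [_rule(["drug00", "drug05"], "ae00", "positive")]
        strict = evaluate_against_truth(rules, self.TRUTH, two_drug_rule="all")
        loose = evaluate_against_truth(rules, self.TRUTH, two_drug_rule="any")
        assert strict["precision"] == 0.0 and loose["precision"] == 1.0
        # either way, containing the truth drug recalls the pair
        assert strict["recall"] == loose["recall"] == 0.5
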