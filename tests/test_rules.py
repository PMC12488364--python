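"""Rule selection pipeline and rule-as-classifier diagnostics."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from netarm import (AssociationRule, PROFILES, RuleFilter, RuleMetrics,
                    characterize_subgroup, evaluate_rule_as_classifier,
                    filter_rules, item_frequency, rank_rules,
                    remove_redundant, select_rules)
from netarm.rules import round_half_away

from conftest import make_db
from oracles import brute_force_2x2


def _rule(lhs, rhs=("PD",), support=25, conf=0.9, lift=1.5):
    n = 115
    return AssociationRule(tuple(lhs), tuple(rhs),
                           RuleMetrics(support, support / n, conf, lift))


class TestFilter:
    def test_support_boundary_is_strict(self):
        f = PROFILES["sinet_pd"]  # support >20
        assert not f.accepts(_rule(("A",), support=20))
        assert f.accepts(_rule(("A",), support=21))

    def test_lift_and_confidence_boundaries_are_inclusive(self):
        f = PROFILES["sinet_pd"]  # lift >=1.2, confidence >=0.70
        assert f.accepts(_rule(("A",), lift=1.2, conf=0.70))
        assert not f.accepts(_rule(("A",), lift=1.1999))
        assert not f.accepts(_rule(("A",), conf=0.6999))

    @given(seed=st.integers(0, 10_000))
    def test_survivors_satisfy_every_predicate(self, seed):
        rng = np.random.default_rng(seed)
        rules = [
            _rule((f"X{i}",), support=int(rng.integers(0, 40)),
                  conf=float(rng.random()), lift=float(rng.random() * 3))
            for i in range(30)
        ]
        f = RuleFilter(min_support_count=15, min_confidence=0.5, min_lift=1.0)
        out = filter_rules(rules, f)
        assert set(map(id, out)) <= set(map(id, rules))
        for r in out:
            assert r.metrics.support_count > 15
            assert r.metrics.confidence >= 0.5
            assert r.metrics.lift >= 1.0


class TestRedundancy:
    def test_permuted_lhs_collapses_to_one_rule(self):
        base = ("female", "CgA > 4 ULN", "Ki-67 > 5%")
        for k in (2, 3):
            perms = list(permutations(base[:k]))
            rules = [_rule(p) for p in perms]
            out = remove_redundant(rules)
            assert len(out) == 1
            assert out[0].lhs == tuple(sorted(base[:k]))

    def test_idempotent_on_unique_rules(self):
        rules = [_rule(("A",)), _rule(("B",))]
        once = remove_redundant(rules)
        assert remove_redundant(once) == once
        assert len(once) == 2


class TestRanking:
    def test_equal_lift_breaks_on_support(self):
        hi = _rule(("A",), support=26, lift=2.08)
        lo = _rule(("B",), support=25, lift=2.08)
        assert rank_rules([lo, hi]) == [hi, lo]

    def test_single_rule(self):
        r = _rule(("A",))
        assert rank_rules([r]) == [r]

    @given(seed=st.integers(0, 10_000))
    def test_output_is_monotone_permutation(self, seed):
        rng = np.random.default_rng(seed)
        rules = [
            _rule((f"X{i}",), support=int(rng.integers(1, 40)),
                  lift=float(rng.choice([1.0, 1.5, 2.0])))
            for i in range(20)
        ]
        out = rank_rules(rules)
        assert sorted(map(id, out)) == sorted(map(id, rules))
        keys = [(-r.metrics.lift, -r.metrics.support_count, r.lhs) for r in out]
        assert keys == sorted(keys)


class TestItemFrequency:
    def test_counts_per_lhs_item(self):
        table = item_frequency([_rule(("A", "B")), _rule(("A",))])
        assert dict(zip(table["item"], table["n_rules"])) == {"A": 2, "B": 1}
        assert table.iloc[0]["item"] == "A"

    def test_empty_rule_set(self):
        assert item_frequency([]).empty


class TestCharacterizeSubgroup:
    def test_reported_lift_arithmetic(self):
        # 23/115 target-positive; antecedent occurs 16 times, 15 with target
        target = {"female", "CgA > 4 ULN"}
        tx = []
        for i in range(115):
            items = set()
            if i < 23:
                items |= target | {"PD"}
            if i < 15 or i == 30:
                items.add("Ki-67 > 5%")
            tx.append(items)
        db = make_db(tx)
        rules = characterize_subgroup(db, target, PROFILES["characterization"])
        (rule,) = [r for r in rules if r.lhs == ("Ki-67 > 5%",)]
        assert rule.metrics.support_count == 15
        assert rule.metrics.confidence == pytest.approx(0.9375)
        assert rule.metrics.lift == pytest.approx(4.6875)
        assert round(rule.metrics.lift, 2) == 4.69

    def test_perfect_cooccurrence_gives_lift_n_over_count(self):
        target = {"female", "CgA > 4 ULN"}
        tx = [target | {"X", "PD"} if i < 10 else {"SD"} for i in range(40)]
        db = make_db(tx)
        f = RuleFilter(min_support_count=5, support_strict=False,
                       min_confidence=0.9, min_lift=0.0)
        rules = characterize_subgroup(db, target, f)
        (rule,) = [r for r in rules if r.lhs == ("X",)]
        assert rule.metrics.confidence == 1.0
        assert rule.metrics.lift == pytest.approx(40 / 10)

    def test_absent_target_is_an_error(self):
        db = make_db([{"A", "PD"}])
        with pytest.raises(ValueError, match="absent"):
            characterize_subgroup(db, {"female"}, PROFILES["characterization"])


class TestDiagnostics:
    def test_reported_female_stratum_worked_example(self):
        # female stratum: 23 rule-positive all PD; negatives 9 PD / 15 SD
        tx, oc = [], []
        for _ in range(23):
            tx.append({"female", "CgA > 4 ULN", "PD"})
        for _ in range(9):
            tx.append({"female", "PD"})
        for _ in range(15):
            tx.append({"female", "SD"})
        tx.append({"male", "CgA > 4 ULN", "SD"})  # outside the stratum
        db = make_db(tx)
        dm = evaluate_rule_as_classifier(["CgA > 4 ULN"], "PD", db,
                                         stratum="female")
        assert (dm.tp, dm.fp, dm.fn, dm.tn) == (23, 0, 9, 15)
        pct = dm.as_percentages()
        assert pct["ppv"] == 100
        assert pct["npv"] == 63  # 15/24 = 62.5 rounded half away from zero
        assert pct["sensitivity"] == 72  # 23/32

    def test_all_positive_leaves_npv_undefined(self):
        db = make_db([{"A", "PD"}, {"A", "SD"}])
        dm = evaluate_rule_as_classifier(["A"], "PD", db)
        assert dm.npv is None
        assert dm.as_percentages()["npv"] is None

    def test_empty_stratum_is_an_error(self):
        db = make_db([{"A", "PD"}])
        with pytest.raises(ValueError, match="absent|empty"):
            evaluate_rule_as_classifier(["A"], "PD", db, stratum="female")

    @given(seed=st.integers(0, 10_000))
    def test_counts_match_brute_force_and_identities_hold(self, seed):
        rng = np.random.default_rng(seed)
        tx = []
        for _ in range(int(rng.integers(3, 30))):
            items = {x for x in "ABC" if rng.random() < 0.5}
            items.add("PD" if rng.random() < 0.5 else "SD")
            tx.append(items)
        db = make_db(tx)
        dm = evaluate_rule_as_classifier(["A"], "PD", db)
        assert (dm.tp, dm.fp, dm.fn, dm.tn) == brute_force_2x2(
            db.transactions, ["A"], "PD")
        assert dm.n == db.N
        if dm.ppv is not None:
            assert dm.ppv * (dm.tp + dm.fp) == pytest.approx(dm.tp)
        if dm.sensitivity is not None and dm.specificity is not None:
            prev = (dm.tp + dm.fn) / dm.n
            positive_rate = (dm.tp + dm.fp) / dm.n
            assert dm.sensitivity * prev + (1 - dm.specificity) * (1 - prev) \
                == pytest.approx(positive_rate)


def test_pipeline_is_deterministic_and_idempotent():
    rules = [_rule((x,), support=s, lift=l)
             for x, s, l in [("A", 25, 2.0), ("B", 30, 1.1), ("C", 22, 1.5),
                             ("A", 25, 2.0)]]
    f = RuleFilter(min_support_count=20, min_confidence=0.5, min_lift=1.2)
    once = select_rules(rules, f)
    assert select_rules(once, f) == once
    assert [r.lhs for r in once] == [("A",), ("C",)]


@pytest.mark.parametrize("x,expected", [
    (62.5, 63), (2.5, 3), (-2.5, -3), (71.875, 72), (0.4, 0)])
def test_round_half_away_from_zero(x, expected):
    assert round_half_away(x) == expected
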