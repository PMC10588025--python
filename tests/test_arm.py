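"""FP-Growth mining: hand-derived examples, oracle equivalence, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import itemset_key, random_transaction_set
from rxmine.arm import (
    brute_force_itemsets,
    build_fp_tree,
    compute_prevalence,
    find_frequent_items,
    generate_rules,
    mine_frequent_itemsets,
    mine_rules,
    support_count_threshold,
)
from rxmine.config import MiningConfig
from rxmine.transactions import TransactionSet


def ts_of(*baskets, n_diabetic=0):
    items = [frozenset(b) for b in baskets]
    return TransactionSet(
        level=5,
        patient_ids=[str(i) for i in range(len(items))],
        items=items,
        n_diabetic=n_diabetic,
    )


class TestFrequentItems:
    def test_hand_counted_example(self):
        out = find_frequent_items(
            [frozenset("ab"), frozenset("a"), frozenset("abc")], min_count=2
        )
        assert out == [("a", 3), ("b", 2)]  # c occurs once, below 0.5 support

    def test_unanimous_item_at_full_support(self):
        trans = [frozenset({"x", c}) for c in "pqr"]
        out = find_frequent_items(trans, min_count=3)
        assert out == [("x", 3)]

    def test_empty_input(self):
        assert find_frequent_items([], min_count=1) == []

    def test_tie_break_is_lexicographic(self):
        out = find_frequent_items([frozenset("ba")], min_count=1)
        assert out == [("a", 1), ("b", 1)]


class TestFPTree:
    def test_identical_transactions_share_one_path(self):
        tree = build_fp_tree([frozenset("ab")] * 2, ["a", "b"])
        a = tree.root.children["a"]
        assert a.count == 2 and a.children["b"].count == 2
        assert len(tree.root.children) == 1

    def test_shared_prefix_branches(self):
        tree = build_fp_tree([frozenset("ab"), frozenset("ac")], ["a", "b", "c"])
        a = tree.root.children["a"]
        assert a.count == 2
        assert a.children["b"].count == 1 and a.children["c"].count == 1

    def test_infrequent_items_contribute_no_path(self):
        tree = build_fp_tree([frozenset("z")], ["a"])
        assert tree.root.children == {}

    def test_header_chain_counts_sum_to_support(self):
        trans = [frozenset("ab"), frozenset("cb"), frozenset("b")]
        order = [i for i, _ in find_frequent_items(trans, 1)]
        tree = build_fp_tree(trans, order)
        assert tree.item_count("b") == 3


class TestMining:
    def test_hand_enumerated_itemsets(self):
        ts = ts_of("ab", "ab", "a")
        out = mine_frequent_itemsets(ts, MiningConfig(min_support=0.5))
        assert itemset_key(out) == [
            (("a",), 3),
            (("a", "b"), 2),
            (("b",), 2),
        ]

    def test_threshold_above_everything_yields_nothing(self):
        ts = ts_of("ab", "cd")
        assert mine_frequent_itemsets(ts, MiningConfig(min_support=0.9)) == []

    def test_single_transaction_power_set(self):
        ts = ts_of("abc")
        out = mine_frequent_itemsets(ts, MiningConfig(min_support=1.0))
        assert len(out) == 7  # every non-empty subset

    def test_max_itemset_size_truncates(self):
        ts = ts_of("abc")
        out = mine_frequent_itemsets(
            ts, MiningConfig(min_support=1.0, max_itemset_size=2)
        )
        assert max(len(fi.items) for fi in out) == 2

    def test_empty_transaction_set(self):
        ts = TransactionSet(level=5, patient_ids=[], items=[])
        assert mine_frequent_itemsets(ts) == []


class TestBruteForceOracle:
    def test_guard_refuses_too_many_items(self):
        ts = ts_of([f"i{k}" for k in range(21)])
        with pytest.raises(ValueError, match="guard"):
            brute_force_itemsets(ts, MiningConfig(min_support=0.5))

    def test_small_instance_matches_fp_growth(self):
        ts = ts_of("ab", "ab", "a", "bc")
        cfg = MiningConfig(min_support=0.25)
        assert itemset_key(brute_force_itemsets(ts, cfg)) == itemset_key(
            mine_frequent_itemsets(ts, cfg)
        )

    def test_randomized_equivalence(self):
        rng = np.random.default_rng(20260926)
        for _ in range(40):
            ts = random_transaction_set(rng, max_transactions=60, max_items=8)
            cfg = MiningConfig(min_support=float(rng.uniform(0.05, 0.6)))
            assert itemset_key(brute_force_itemsets(ts, cfg)) == itemset_key(
                mine_frequent_itemsets(ts, cfg)
            )


class TestRules:
    def test_hand_computed_rule_metrics(self):
        """4x{A10,C10}, 2x{A10}, 1x{C10}, 1x{C07}: A10=>C10 has
        support 1/2, confidence 2/3, lift 16/15."""
        ts = ts_of(*(["AC"] * 4 + ["A"] * 2 + ["C"] + ["B"]), n_diabetic=6)
        cfg = MiningConfig(min_support=0.1, min_confidence=0.1)
        rules = {
            (tuple(sorted(r.antecedent)), r.consequent): r for r in mine_rules(ts, cfg)
        }
        r = rules[(("A",), "C")]
        assert r.joint_count == 4
        assert r.support == pytest.approx(0.5, abs=1e-15)
        assert r.confidence == pytest.approx(4 / 6, abs=1e-15)
        assert r.lift == pytest.approx((4 / 6) / (5 / 8), abs=1e-15)

    def test_perfect_co_occurrence(self):
        ts = ts_of("xy", "xy", "a", "b")
        rules = mine_rules(ts, MiningConfig(min_support=0.25, min_confidence=0.5))
        r = next(r for r in rules if r.consequent == "y")
        assert r.confidence == 1.0 and r.lift == 2.0

    def test_single_item_consequents_only(self, pipeline_result, app_config):
        rules = mine_rules(pipeline_result.transactions(2), app_config.mining)
        assert all(isinstance(r.consequent, str) for r in rules)
        assert all(r.consequent not in r.antecedent for r in rules)

    def test_confidence_threshold_filters(self):
        ts = ts_of("ab", "a", "a", "a")
        cfg_low = MiningConfig(min_support=0.1, min_confidence=0.1)
        cfg_high = MiningConfig(min_support=0.1, min_confidence=0.5)
        assert len(mine_rules(ts, cfg_low)) > len(mine_rules(ts, cfg_high))


class TestPrevalence:
    def test_division(self):
        # 4 of 8 patients hold both drugs; 6 patients are diabetic
        ts = ts_of(*(["ab"] * 4 + [""] * 4), n_diabetic=6)
        rules = mine_rules(ts, MiningConfig(min_support=0.5, min_confidence=0.1))
        r = next(r for r in rules if r.consequent == "b")
        assert r.joint_count == 4
        assert compute_prevalence(r, ts) == pytest.approx(4 / 6)

    def test_saturation(self):
        ts = ts_of("ab", "ab", n_diabetic=2)
        r = mine_rules(ts, MiningConfig(min_support=0.5, min_confidence=0.1))[0]
        assert compute_prevalence(r, ts) == 1.0

    def test_recoverable_from_support_and_n(self):
        """support 0.001 of N=10,000 gives sigma=10, prevalence 10/1000."""
        n, n_diab = 10_000, 1_000
        items = [frozenset("ab")] * 10 + [frozenset()] * (n - 10)
        ts = TransactionSet(
            level=5, patient_ids=[str(i) for i in range(n)], items=items,
            n_diabetic=n_diab,
        )
        r = mine_rules(ts, MiningConfig(min_support=0.0005, min_confidence=0.1))[0]
        assert r.support == pytest.approx(0.001)
        assert compute_prevalence(r, ts) == pytest.approx(0.01)
        assert r.support * ts.n_patients / ts.n_diabetic == pytest.approx(0.01)

    def test_undefined_without_diabetics(self):
        ts = ts_of("ab")
        r = mine_rules(ts, MiningConfig(min_support=0.5, min_confidence=0.1))[0]
        with pytest.raises(ValueError):
            compute_prevalence(r, ts)


class TestInvariants:
    def test_downward_closure(self, pipeline_result, app_config):
        itemsets = mine_frequent_itemsets(
            pipeline_result.transactions(2), app_config.mining
        )
        counts = {fi.items: fi.support_count for fi in itemsets}
        for s, c in counts.items():
            for item in s:
                sub = s - {item}
                if sub:
                    assert counts[sub] >= c

    @given(st.integers(min_value=0, max_value=6))
    @settings(max_examples=7, deadline=None)
    def test_threshold_anti_monotone(self, step):
        rng = np.random.default_rng(400 + step)
        ts = random_transaction_set(rng, max_transactions=80, max_items=8)
        lo, hi = 0.05 + 0.1 * step, 0.15 + 0.1 * step
        s_lo = {fi.items for fi in mine_frequent_itemsets(ts, MiningConfig(min_support=lo))}
        s_hi = {fi.items for fi in mine_frequent_itemsets(ts, MiningConfig(min_support=hi))}
        assert s_hi <= s_lo
        r_lo = {(r.antecedent, r.consequent) for r in mine_rules(ts, MiningConfig(min_support=lo, min_confidence=0.2))}
        r_hi = {(r.antecedent, r.consequent) for r in mine_rules(ts, MiningConfig(min_support=lo, min_confidence=0.6))}
        assert r_hi <= r_lo

    def test_metric_identities_on_mined_rules(self, pipeline_result, app_config):
        ts = pipeline_result.transactions(3)
        itemsets = mine_frequent_itemsets(ts, app_config.mining)
        counts = {fi.items: fi.support_count for fi in itemsets}
        rules = generate_rules(itemsets, ts, app_config.mining)
        n = ts.n_patients
        for r in rules:
            supp_a = counts[r.antecedent] / n
            supp_b = counts[frozenset((r.consequent,))] / n
            assert r.support == pytest.approx(r.joint_count / n, abs=1e-12)
            assert r.confidence == pytest.approx(r.support / supp_a, abs=1e-12)
            assert r.lift * supp_b == pytest.approx(r.confidence, abs=1e-12)
            assert r.support <= min(supp_a, supp_b) + 1e-15
            assert r.prevalence == pytest.approx(
                r.joint_count / ts.n_diabetic, abs=1e-12
            )


def test_support_count_threshold_rounds_up():
    assert support_count_threshold(0.5, 3) == 2
    assert support_count_threshold(0.5, 4) == 2  # non-strict at the boundary
    assert support_count_threshold(1e-4, 50_000) == 5
    assert support_count_threshold(1e-9, 10) == 1
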