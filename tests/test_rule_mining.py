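"""Fuzzy Apriori: supports, confidences, levelwise mining, filtering, pruning.

The crisp-reduction oracle is central here: on any 0/1 membership table the
fuzzy machinery must reproduce classical Apriori exactly, so small instances
are checked against brute-force enumeration over all itemsets.
"""

from itertools import combinations

import numpy as np
import pytest

from farmstress.rule_mining import (
    AssociationRule,
    FuzzyItem,
    FuzzyTransaction,
    MiningInputError,
    build_transactions,
    chi_square_filter,
    f_confidence,
    f_support,
    load_rules,
    mine_rules,
    parse_rule_line,
    prune_redundant,
    save_rules,
)

A = FuzzyItem("V1", "a")
B = FuzzyItem("V2", "b")


def txn(rid, degrees):
    return FuzzyTransaction(rid, degrees)


@pytest.fixture()
def toy_txns():
    return [
        txn("t1", {A: 0.8, B: 0.6}),
        txn("t2", {A: 0.4, B: 1.0}),
    ]


class TestSupportConfidence:
    def test_two_transaction_worked_example(self, toy_txns):
        assert f_support({A, B}, toy_txns) == pytest.approx(0.5)
        assert f_support({A}, toy_txns) == pytest.approx(0.6)

    def test_confidence_worked_example(self, toy_txns):
        assert f_confidence({A}, B, toy_txns) == pytest.approx(0.5 / 0.6)

    def test_inclusion_gives_confidence_one(self):
        txns = [txn("t1", {A: 0.3, B: 0.5}), txn("t2", {A: 0.9, B: 0.95})]
        assert f_confidence({A}, B, txns) == pytest.approx(1.0)

    def test_full_membership_support_one(self):
        txns = [txn("t1", {A: 1.0, B: 1.0})] * 3
        assert f_support({A, B}, txns) == 1.0

    def test_empty_inputs_rejected(self, toy_txns):
        with pytest.raises(MiningInputError):
            f_support(set(), toy_txns)
        with pytest.raises(MiningInputError):
            f_support({A}, [])

    def test_zero_antecedent_support_rejected(self):
        txns = [txn("t1", {A: 0.0, B: 1.0})]
        with pytest.raises(MiningInputError):
            f_confidence({A}, B, txns)

    def test_support_bounded_by_item_supports(self, toy_txns):
        joint = f_support({A, B}, toy_txns)
        assert joint <= f_support({A}, toy_txns)
        assert joint <= f_support({B}, toy_txns)


# ---------------------------------------------------------------------------
# crisp-reduction oracle: brute-force classical Apriori
# ---------------------------------------------------------------------------

def classical_rules(table, items, min_support, min_confidence, outcome_var):
    """Enumerate every antecedent -> outcome rule on a 0/1 table."""
    n = len(table)

    def supp(idx):
        return sum(all(row[i] for i in idx) for row in table) / n

    out = []
    outcome_idx = [i for i, it in enumerate(items) if it.variable == outcome_var]
    other_idx = [i for i, it in enumerate(items) if it.variable != outcome_var]
    for c in outcome_idx:
        for r in range(1, len(other_idx) + 1):
            for ant in combinations(other_idx, r):
                if len({items[i].variable for i in ant}) != r:
                    continue
                s_ant = supp(ant)
                s_all = supp(ant + (c,))
                if s_all < min_support or s_ant == 0:
                    continue
                conf = s_all / s_ant
                if conf < min_confidence:
                    continue
                out.append(
                    (
                        frozenset(items[i] for i in ant),
                        items[c],
                        round(s_all, 12),
                        round(conf, 12),
                    )
                )
    return set(out)


def crisp_transactions(table, items):
    return [
        txn(f"t{k}", {it: float(v) for it, v in zip(items, row)})
        for k, row in enumerate(table)
    ]


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_crisp_reduction_matches_bruteforce_apriori(seed):
    """On random 0/1 tables (<=6 items over 3 variables, <=12 transactions)
    mining equals exhaustive classical Apriori at the same thresholds."""
    rng = np.random.default_rng(seed)
    items = [
        FuzzyItem("V1", "a"), FuzzyItem("V1", "b"),
        FuzzyItem("V2", "c"), FuzzyItem("V2", "d"),
        FuzzyItem("WRS", "x"), FuzzyItem("WRS", "y"),
    ]
    n = int(rng.integers(4, 13))
    table = (rng.random((n, len(items))) < 0.55).astype(int)
    txns = crisp_transactions(table, items)
    min_s, min_c = 0.2, 0.5
    mined = {
        (r.antecedent, r.consequent, round(r.support, 12), round(r.confidence, 12))
        for r in mine_rules(txns, min_s, min_c, max_antecedent=4)
    }
    assert mined == classical_rules(table, items, min_s, min_c, "WRS")


def test_crisp_support_equals_counting():
    rng = np.random.default_rng(7)
    items = [A, B]
    table = (rng.random((10, 2)) < 0.5).astype(int)
    txns = crisp_transactions(table, items)
    expected = np.mean(table[:, 0] & table[:, 1])
    if expected > 0:
        assert f_support({A, B}, txns) == pytest.approx(expected)


class TestMineRules:
    def test_threshold_above_max_item_support_yields_nothing(self, toy_txns):
        assert mine_rules(toy_txns, min_support=0.95, min_confidence=0.0) == []

    def test_transaction_order_invariance(self):
        rng = np.random.default_rng(11)
        items = [A, B, FuzzyItem("WRS", "x")]
        txns = [
            txn(f"t{k}", {it: float(d) for it, d in zip(items, row)})
            for k, row in enumerate(rng.random((20, 3)))
        ]
        fwd = mine_rules(txns, 0.1, 0.2)
        rev = mine_rules(txns[::-1], 0.1, 0.2)
        assert [(r.antecedent, r.consequent) for r in fwd] == [
            (r.antecedent, r.consequent) for r in rev
        ]
        # summation order may differ in the last ulp only
        for a, b in zip(fwd, rev):
            assert a.support == pytest.approx(b.support, abs=1e-12)
            assert a.confidence == pytest.approx(b.confidence, abs=1e-12)

    def test_downward_closure_exhaustive_small_instance(self):
        rng = np.random.default_rng(5)
        items = [
            FuzzyItem(v, t) for v, ts in [("V1", "ab"), ("V2", "cd"), ("WRS", "x")]
            for t in ts
        ]
        txns = [
            txn(f"t{k}", {it: float(d) for it, d in zip(items, row)})
            for k, row in enumerate(rng.random((12, len(items))))
        ]
        threshold = 0.15
        by_var = {}
        for it in items:
            by_var.setdefault(it.variable, []).append(it)
        # every cross-variable itemset: subsets of a frequent set are frequent
        import itertools

        for combo in itertools.product(*[[None, *v] for v in by_var.values()]):
            itemset = {it for it in combo if it is not None}
            if len(itemset) < 2:
                continue
            if f_support(itemset, txns) >= threshold:
                for r in range(1, len(itemset)):
                    for sub in combinations(itemset, r):
                        assert f_support(set(sub), txns) >= threshold

    def test_rule_annotations_consistent(self, variables, profile_factory):
        rng = np.random.default_rng(2)
        profiles = profile_factory(rng.random((50, 5)))
        txns = build_transactions(profiles, variables)
        rules = mine_rules(txns, 0.02, 0.1, max_antecedent=2)
        assert rules, "expected some rules on random data at loose thresholds"
        for r in rules[:20]:
            s_ant = f_support(r.antecedent, txns)
            s_all = f_support(set(r.antecedent) | {r.consequent}, txns)
            assert r.confidence * s_ant == pytest.approx(s_all, abs=1e-9)
            assert r.support <= min(
                f_support({it}, txns) for it in set(r.antecedent) | {r.consequent}
            ) + 1e-12


class TestBuildTransactions:
    def test_partition_of_unity_per_variable(self, variables, profile_factory):
        rng = np.random.default_rng(9)
        profiles = profile_factory(rng.random((5, 5)))
        for t in build_transactions(profiles, variables):
            per_var = {}
            for item, d in t.degrees.items():
                per_var[item.variable] = per_var.get(item.variable, 0.0) + d
            for var, total in per_var.items():
                assert total == pytest.approx(1.0)

    def test_profile_at_peaks_is_crisp(self, variables, profile_factory):
        profiles = profile_factory([[0.0, 0.5, 1.0, 0.5, 0.5]])
        (t,) = build_transactions(profiles, variables)
        assert t.degree(FuzzyItem("PCG", "normal mental health")) == 1.0
        assert t.degree(FuzzyItem("FIN", "not changed")) == 1.0
        assert t.degree(FuzzyItem("SCF", "strong association")) == 1.0
        assert t.degree(FuzzyItem("WRS", "moderate")) == 1.0

    def test_missing_outcome_rejected(self, variables, profile_factory):
        profiles = profile_factory([[0.5, 0.5, 0.5, 0.5]], with_wrs=False)
        with pytest.raises(MiningInputError):
            build_transactions(profiles, variables)


class TestChiSquare:
    def test_perfect_cooccurrence_retained(self):
        txns = [txn(f"t{k}", {A: 1.0, B: 1.0}) for k in range(20)]
        txns += [txn(f"u{k}", {A: 0.0, B: 0.0}) for k in range(20)]
        rule = AssociationRule(frozenset([A]), B)
        kept = chi_square_filter([rule], txns, alpha=0.05)
        assert len(kept) == 1
        assert kept[0].chi2_p < 1e-6

    def test_single_transaction_untestable(self):
        txns = [txn("t0", {A: 1.0, B: 1.0})]
        rule = AssociationRule(frozenset([A]), B)
        assert chi_square_filter([rule], txns, alpha=0.05) == []

    def test_independent_items_rejected_near_alpha_rate(self):
        """Retention rate of a null association stays near alpha across seeds."""
        kept = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            a = rng.random(200) < 0.5
            b = rng.random(200) < 0.5
            txns = [
                txn(f"t{k}", {A: float(x), B: float(y)})
                for k, (x, y) in enumerate(zip(a, b))
            ]
            rule = AssociationRule(frozenset([A]), B)
            kept += len(chi_square_filter([rule], txns, alpha=0.05))
        assert kept / reps <= 0.15  # ~alpha with continuity correction, some slack


class TestPruneRedundant:
    C = FuzzyItem("WRS", "x")

    def _rule(self, ants, conf):
        return AssociationRule(frozenset(ants), self.C, support=0.5, confidence=conf)

    def test_dominated_specialisation_removed(self):
        general = self._rule([A], 0.9)
        special = self._rule([A, B], 0.8)
        assert prune_redundant([general, special]) == [general]

    def test_improving_specialisation_kept(self):
        general = self._rule([A], 0.7)
        special = self._rule([A, B], 0.9)
        kept = prune_redundant([special, general])  # mined order: conf desc
        assert set(kept) == {general, special}

    def test_matches_bruteforce_dominance_filter(self):
        rng = np.random.default_rng(3)
        pool = [A, B, FuzzyItem("V3", "e")]
        rules = []
        for r in range(1, 4):
            for ants in combinations(pool, r):
                rules.append(self._rule(ants, float(rng.random())))
        rules.sort(key=lambda r: -r.confidence)
        kept = prune_redundant(rules)
        # brute force: iteratively remove any rule dominated by a kept rule
        expected = []
        for rule in rules:
            if not any(
                k.antecedent < rule.antecedent and k.confidence >= rule.confidence
                for k in expected
            ):
                expected.append(rule)
        assert kept == expected


class TestRuleBaseFile:
    def test_bit_exact_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        rules = [
            AssociationRule(
                frozenset([A, B]),
                FuzzyItem("WRS", "x"),
                support=float(rng.random()),
                confidence=float(rng.random()),
                lift=float(rng.random() * 3),
                chi2_p=float(rng.random()),
            )
            for _ in range(5)
        ]
        path = tmp_path / "rules.frb"
        save_rules(rules, path)
        loaded = load_rules(path)
        assert loaded == rules
        save_rules(loaded, tmp_path / "again.frb")
        assert (tmp_path / "again.frb").read_text() == path.read_text()

    def test_unknown_term_reported_with_rule_index(self, tmp_path, variables):
        path = tmp_path / "bad.frb"
        path.write_text("PCG=bogus_term => WRS=low | support=0.1\n")
        with pytest.raises(ValueError, match="rule 1"):
            load_rules(path, variables)
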