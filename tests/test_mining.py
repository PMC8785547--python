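import numpy as np
import pytest

from extrae import (
    AssociationRule,
    MiningParams,
    TransactionDataset,
    compute_features,
    generate_rules,
    mine_frequent_itemsets,
)
from extrae.mining import (
    FEATURE_NAMES,
    read_rules_tsv,
    rules_from_frame,
    rules_to_frame,
    write_rules_tsv,
)

from conftest import random_dataset
from oracles import brute_frequent_itemsets, brute_rules

PERMISSIVE = MiningParams(
    min_support=0.2,
    min_confidence=0.1,
    min_lift=0.0,
    max_antecedent_len=4,
    max_consequent_len=3,
)


class TestMineFrequentItemsets:
    def test_all_identical_corpus(self):
        ds = TransactionDataset.from_iterable([{"A", "B"}] * 4)
        its = mine_frequent_itemsets(ds, 0.5)
        assert {(tuple(sorted(i.items)), i.support) for i in its} == {
            (("A",), 1.0),
            (("B",), 1.0),
            (("A", "B"), 1.0),
        }

    def test_no_universal_item(self):
        ds = TransactionDataset.from_iterable([{"A"}, {"B"}])
        assert mine_frequent_itemsets(ds, 1.0) == []

    def test_counts_are_exact(self, tiny_ds):
        its = {frozenset(i.items): i.count for i in mine_frequent_itemsets(tiny_ds, 0.2)}
        assert its[frozenset("A")] == 3
        assert its[frozenset("B")] == 3
        assert its[frozenset("AB")] == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_powerset_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n_items=6, n_transactions=50)
        min_support = float(rng.uniform(0.05, 0.4))
        got = {i.items: i.count for i in mine_frequent_itemsets(ds, min_support)}
        assert got == brute_frequent_itemsets(ds.transactions, min_support)

    def test_anti_monotone(self):
        rng = np.random.default_rng(42)
        ds = random_dataset(rng, n_items=8, n_transactions=80)
        its = mine_frequent_itemsets(ds, 0.1)
        freq = {i.items for i in its}
        for i in its:
            for item in i.items:
                if len(i.items) > 1:
                    assert (i.items - {item}) in freq

    def test_canonical_order(self):
        rng = np.random.default_rng(1)
        ds = random_dataset(rng, n_items=6, n_transactions=40)
        its = mine_frequent_itemsets(ds, 0.1)
        keys = [(len(i.items), tuple(sorted(i.items))) for i in its]
        assert keys == sorted(keys)

    def test_bad_support_rejected(self, tiny_ds):
        with pytest.raises(ValueError):
            mine_frequent_itemsets(tiny_ds, 0.0)


class TestGenerateRules:
    def test_degenerate_corpus_inclusive_lift(self):
        ds = TransactionDataset.from_iterable([{"A", "B"}] * 4)
        its = mine_frequent_itemsets(ds, 0.5)
        rules = generate_rules(its, ds, MiningParams(0.5, 0.7, 1.0, 4, 1))
        got = {(tuple(sorted(r.antecedent)), tuple(sorted(r.consequent))) for r in rules}
        assert got == {(("A",), ("B",)), (("B",), ("A",))}
        for r in rules:
            assert (r.support, r.confidence, r.lift) == (1.0, 1.0, 1.0)

    def test_consequent_length_cap(self):
        rng = np.random.default_rng(2)
        ds = random_dataset(rng, n_items=7, n_transactions=60)
        its = mine_frequent_itemsets(ds, 0.05)
        rules = generate_rules(its, ds, MiningParams(0.05, 0.2, 0.0, 4, 1))
        assert rules and all(len(r.consequent) == 1 for r in rules)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bipartition_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        ds = random_dataset(rng, n_items=6, n_transactions=50)
        its = mine_frequent_itemsets(ds, PERMISSIVE.min_support)
        rules = generate_rules(its, ds, PERMISSIVE)
        got = {
            (r.antecedent, r.consequent): (r.support, r.confidence, r.lift)
            for r in rules
        }
        expected = brute_rules(
            ds.transactions,
            PERMISSIVE.min_support,
            PERMISSIVE.min_confidence,
            PERMISSIVE.min_lift,
            PERMISSIVE.max_antecedent_len,
            PERMISSIVE.max_consequent_len,
        )
        assert got == expected

    def test_measure_identities(self):
        """confidence = supp(Z)/supp(X) and lift = confidence/supp(Y), recounted."""
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, n_items=6, n_transactions=70)
        its = mine_frequent_itemsets(ds, 0.1)
        rules = generate_rules(its, ds, MiningParams(0.1, 0.3, 0.0, 4, 2))
        n = ds.n_transactions
        assert rules
        for r in rules:
            cz = sum(1 for t in ds.transactions if r.items <= t)
            cx = sum(1 for t in ds.transactions if r.antecedent <= t)
            cy = sum(1 for t in ds.transactions if r.consequent <= t)
            assert r.support == cz / n
            assert r.confidence == pytest.approx(cz / cx, rel=1e-12)
            assert r.lift == pytest.approx((cz / cx) / (cy / n), rel=1e-12)

    def test_canonical_rule_order(self):
        rng = np.random.default_rng(4)
        ds = random_dataset(rng, n_items=6, n_transactions=50)
        its = mine_frequent_itemsets(ds, 0.1)
        rules = generate_rules(its, ds, MiningParams(0.1, 0.2, 0.0, 4, 2))
        keys = [(-r.support, r.key()) for r in rules]
        assert keys == sorted(keys)


class TestComputeFeatures:
    def test_lift_from_prior_and_posterior_confidence(self):
        """Consequent baseline 60%, rule confidence 72% -> lift 1.2."""
        transactions = []
        transactions += [{"cough", "flu"}] * 18
        transactions += [{"cough"}] * 7
        transactions += [{"flu"}] * 42
        transactions += [{"other"}] * 33
        ds = TransactionDataset.from_iterable(transactions)
        its = mine_frequent_itemsets(ds, 0.1)
        rules = generate_rules(its, ds, MiningParams(0.1, 0.7, 1.0, 4, 1))
        (rule,) = [r for r in rules if r.antecedent == frozenset({"cough"})]
        f = compute_features(rule)
        assert f.confidence == 0.72
        assert f.lift == 1.2

    def test_structural_counts(self):
        rule = AssociationRule(frozenset("AB"), frozenset("C"), 0.2, 0.8, 1.5)
        f = compute_features(rule)
        assert (f.n_antecedents, f.n_consequents) == (2, 1)
        assert f.to_array().tolist() == [0.2, 0.8, 1.5, 2.0, 1.0]
        assert len(FEATURE_NAMES) == 5

    def test_independent_items_have_unit_lift(self):
        # A and B occur independently in counts: supp(AB) = supp(A)supp(B)
        transactions = (
            [{"A", "B"}] * 1, [{"A"}] * 1, [{"B"}] * 1, [{"z"}] * 1
        )
        ds = TransactionDataset.from_iterable([t for grp in transactions for t in grp])
        its = mine_frequent_itemsets(ds, 0.25)
        rules = generate_rules(its, ds, MiningParams(0.25, 0.1, 0.0, 4, 1))
        ab = [r for r in rules if r.antecedent == frozenset("A") and r.consequent == frozenset("B")]
        assert ab[0].lift == 1.0


class TestRuleTsv:
    def test_round_trip(self, tmp_path):
        rules = [
            AssociationRule(frozenset({"a", "b"}), frozenset({"c"}), 0.25, 0.8, 2.0),
            AssociationRule(frozenset({"c"}), frozenset({"a"}), 0.125, 0.75, 1.5),
        ]
        df = rules_to_frame(rules, p_values=[1e-8, 0.3], labels=[True, False])
        path = tmp_path / "rules.tsv"
        write_rules_tsv(df, path)
        back = read_rules_tsv(path)
        assert rules_from_frame(back) == rules
        assert back["label"].tolist() == [True, False]
        assert back["p_value"].tolist() == pytest.approx([1e-8, 0.3], rel=1e-5)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("antecedent\tconsequent\na\tb\n")
        with pytest.raises(ValueError, match="missing rule columns"):
            read_rules_tsv(path)
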