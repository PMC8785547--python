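import numpy as np
import pytest

from extrae import (
    AssociationRule,
    MiningParams,
    default_benchmark_spec,
    generate,
    label_rule,
    labeled_rules_from_corpus,
    model_lift,
)
from extrae.synthetic import (
    PlantedRule,
    SyntheticSpec,
    model_probability,
    run_benchmark,
)


def _rule(ant, cons):
    ant = {ant} if isinstance(ant, str) else set(ant)
    cons = {cons} if isinstance(cons, str) else set(cons)
    return AssociationRule(frozenset(ant), frozenset(cons), 0.1, 0.5, 1.0)


class TestSpecValidation:
    def test_overlapping_components_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SyntheticSpec(
                prevalence={"a": 0.2, "b": 0.2},
                planted=(
                    PlantedRule(("a",), "c", 0.8, 0.1),
                    PlantedRule(("a",), "d", 0.8, 0.1),
                ),
            )

    def test_inverted_effect_rejected(self):
        with pytest.raises(ValueError):
            PlantedRule(("a",), "c", q=0.1, b=0.8)

    def test_out_of_range_prevalence_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(prevalence={"a": 1.5})


class TestGenerate:
    def test_background_frequencies_near_prevalence(self):
        # filler item keeps the empty-redraw truncation negligible
        spec = SyntheticSpec(
            prevalence={"a": 0.5, "b": 0.5, "z": 0.99},
            n_transactions=10000,
            rng_seed=0,
        )
        ds = generate(spec)
        for item in "ab":
            freq = sum(1 for t in ds.transactions if item in t) / len(ds)
            assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / 10000) + 0.01

    def test_deterministic_dependency_at_extremes(self):
        # q ~ 1, b ~ 0: consequent iff antecedent, essentially always
        spec = SyntheticSpec(
            prevalence={"a": 0.5, "z": 0.9},
            planted=(PlantedRule(("a",), "c", q=1 - 1e-12, b=1e-12),),
            n_transactions=3000,
            rng_seed=1,
        )
        ds = generate(spec)
        assert all(("c" in t) == ("a" in t) for t in ds.transactions)

    def test_no_empty_transactions(self):
        spec = SyntheticSpec(
            prevalence={"a": 0.05, "b": 0.05}, n_transactions=500, rng_seed=2
        )
        ds = generate(spec)
        assert all(len(t) >= 1 for t in ds.transactions)
        assert ds.n_transactions == 500

    def test_unsatisfiable_spec_errors(self):
        spec = SyntheticSpec(
            prevalence={"a": 1e-12, "b": 1e-12}, n_transactions=200, rng_seed=3
        )
        with pytest.raises(RuntimeError, match="non-empty"):
            generate(spec, max_retries=3)

    def test_joint_support_matches_closed_form(self, planted_spec):
        spec = SyntheticSpec(
            planted_spec.prevalence, planted_spec.planted, 100000, 7
        )
        ds = generate(spec)
        pr = spec.planted[0]  # a -> c with q
        target = frozenset(pr.antecedent) | {pr.consequent}
        emp = sum(1 for t in ds.transactions if target <= t) / len(ds)
        expected = model_probability(spec, target)
        se = np.sqrt(expected * (1 - expected) / len(ds))
        from extrae.synthetic import model_empty_probability

        bias = expected * model_empty_probability(spec)  # empty-redraw truncation
        assert abs(emp - expected) < 4 * se + 2 * bias


class TestModelLift:
    def test_independent_rules_have_exactly_unit_lift(self):
        spec = SyntheticSpec(prevalence={"a": 0.3, "b": 0.2, "c": 0.4})
        assert model_lift(spec, _rule("a", "b")) == 1.0
        assert model_lift(spec, _rule({"a", "b"}, "c")) == 1.0

    def test_deterministic_dependency_closed_form(self):
        spec = SyntheticSpec(
            prevalence={"a": 0.25, "z": 0.5},
            planted=(PlantedRule(("a",), "c", q=1 - 1e-15, b=1e-15),),
        )
        # q=1, b=0: P(c) = P(a), lift = 1/P(c)
        assert model_lift(spec, _rule("a", "c")) == pytest.approx(4.0, rel=1e-9)

    def test_cross_component_factors_multiply(self, planted_spec):
        # antecedent spans both planted components; consequent in one
        lift_joint = model_lift(planted_spec, _rule({"a", "b", "x"}, "d"))
        lift_within = model_lift(planted_spec, _rule({"b", "x"}, "d"))
        assert lift_joint == pytest.approx(lift_within, rel=1e-12)

    def test_unknown_item_rejected(self, planted_spec):
        with pytest.raises(ValueError, match="unknown item"):
            model_lift(planted_spec, _rule("nope", "a"))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_monte_carlo_lift(self, planted_spec, seed):
        """Closed-form lift vs empirical lift on a large sample."""
        rng = np.random.default_rng(seed)
        n = 200000
        spec = SyntheticSpec(
            planted_spec.prevalence, planted_spec.planted, n, 1000 + seed
        )
        ds = generate(spec)
        items = sorted(spec.prevalence) + [p.consequent for p in spec.planted]
        for _ in range(5):
            x = frozenset(rng.choice(items, size=2, replace=False))
            y = frozenset(rng.choice(sorted(set(items) - x), size=1))
            cx = sum(1 for t in ds.transactions if x <= t)
            cy = sum(1 for t in ds.transactions if y <= t)
            cz = sum(1 for t in ds.transactions if (x | y) <= t)
            if cz < 50:
                continue
            emp = (cz * n) / (cx * cy)
            exact = model_lift(spec, AssociationRule(x, y, 0.1, 0.5, 1.0))
            assert emp == pytest.approx(exact, rel=0.2)


class TestLabelRule:
    def test_planted_rule_is_true(self, planted_spec):
        assert label_rule(planted_spec, _rule("a", "c"))
        assert label_rule(planted_spec, _rule({"b", "x"}, "d"))

    def test_background_pair_is_false(self, planted_spec):
        assert not label_rule(planted_spec, _rule("a", "z"))

    def test_subset_antecedent_of_planted_still_true(self, planted_spec):
        # b alone raises P(d): q > b makes any sub-antecedent positively dependent
        assert label_rule(planted_spec, _rule("b", "d"))

    def test_label_independent_of_corpus(self, planted_spec):
        # depends only on the spec: identical under different corpus seeds
        other = SyntheticSpec(
            planted_spec.prevalence, planted_spec.planted, 100, 999
        )
        r = _rule("a", "c")
        assert label_rule(planted_spec, r) == label_rule(other, r)


class TestBenchmark:
    def test_default_world_yields_both_classes(self, benchmark_rules):
        n_true = sum(r.label for r in benchmark_rules)
        assert len(benchmark_rules) >= 50
        assert 0 < n_true < len(benchmark_rules)

    def test_reproducible_report(self):
        a = run_benchmark(replicates=1, rng_seed=5, seed_sizes=None)
        b = run_benchmark(replicates=1, rng_seed=5, seed_sizes=None)
        assert a.to_json() == b.to_json()

    def test_report_structure(self):
        rep = run_benchmark(replicates=2, rng_seed=6, seed_sizes=(5, 10))
        assert set(rep.per_replicate["method"]) == {
            "unsupervised",
            "supervised",
            "extrae",
        }
        assert len(rep.traces) == 2
        assert rep.seed_size_sweep["seed_size"].tolist() == [5, 10]

    def test_too_few_rules_is_benchmark_error(self):
        tiny = SyntheticSpec(
            prevalence={"a": 0.4, "b": 0.4}, n_transactions=200, rng_seed=0
        )
        with pytest.raises(RuntimeError, match="rules"):
            run_benchmark(spec=tiny, replicates=1, rng_seed=0, seed_sizes=None)
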