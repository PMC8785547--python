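import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from extrae import (
    LabeledRule,
    MiningParams,
    TransactionDataset,
    compute_features,
    labeled_rules_from_corpus,
)
from extrae.synthetic import PlantedRule, SyntheticSpec


@pytest.fixture
def tiny_ds() -> TransactionDataset:
    """Five transactions; rule A->B has the table (2, 1, 1, 1)."""
    return TransactionDataset.from_iterable(
        [{"A", "B"}, {"A", "B"}, {"A"}, {"B"}, {"C"}]
    )


def random_dataset(rng: np.random.Generator, n_items: int, n_transactions: int):
    """A random corpus with clustered item probabilities (non-degenerate)."""
    items = [chr(ord("a") + i) for i in range(n_items)]
    probs = rng.uniform(0.1, 0.8, size=n_items)
    transactions = []
    for _ in range(n_transactions):
        t = {it for it, p in zip(items, probs) if rng.random() < p}
        if not t:
            t = {items[int(rng.integers(n_items))]}
        transactions.append(t)
    return TransactionDataset.from_iterable(transactions)


@pytest.fixture
def planted_spec() -> SyntheticSpec:
    """Small two-dependency world with exact ground truth.

    The high-prevalence fillers z and w keep P(empty transaction) ~ 0.7%,
    so the empty-redraw truncation barely perturbs sampled frequencies.
    """
    return SyntheticSpec(
        prevalence={"a": 0.3, "b": 0.25, "x": 0.2, "z": 0.95, "w": 0.6},
        planted=(
            PlantedRule(("a",), "c", q=0.9, b=0.05),
            PlantedRule(("b", "x"), "d", q=0.8, b=0.1),
        ),
        n_transactions=4000,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def benchmark_rules() -> list[LabeledRule]:
    """One default-world replicate of mined, p-valued, gold-labeled rules."""
    from extrae import default_benchmark_spec

    return labeled_rules_from_corpus(default_benchmark_spec(3), rng_seed=3)
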