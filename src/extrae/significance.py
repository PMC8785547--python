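"""Exact significance of rules: 2x2 contingency tables and Fisher's test.

A rule ``X -> Y`` classifies each transaction two ways — does it contain all
of X, and does it contain all of Y — giving a 2x2 table.  Under the null of
independence with fixed margins the joint-presence cell follows a
hypergeometric distribution; the one-sided (over-representation) p-value is
the upper tail P(cell >= observed).  Only positive dependence between
antecedent and consequent is of interest, so one-sided is the default; the
two-sided variant is exposed as an option.

The holdout procedure guards against false discoveries from mining and
testing on the same data: rules are mined on an exploratory half of the
corpus and their p-values are computed on the disjoint holdout half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .mining import AssociationRule, MiningParams, generate_rules, mine_frequent_itemsets
from .transactions import TransactionDataset

__all__ = [
    "ContingencyTable",
    "PValuedRule",
    "build_contingency",
    "fisher_p",
    "split_exploratory_holdout",
    "holdout_pvalues",
    "classify_by_threshold",
]

#: Smallest positive double; degenerate floor so p stays in (0, 1].
_TINY = 5e-324


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of antecedent-presence x consequent-presence over transactions."""

    n11: int  # antecedent present, consequent present
    n10: int  # antecedent present, consequent absent
    n01: int  # antecedent absent, consequent present
    n00: int  # both absent

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def row1(self) -> int:
        """Antecedent-present margin."""
        return self.n11 + self.n10

    @property
    def col1(self) -> int:
        """Consequent-present margin."""
        return self.n11 + self.n01

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n10], [self.n01, self.n00]])


@dataclass(frozen=True)
class PValuedRule:
    rule: AssociationRule
    p_value: float
    table: ContingencyTable

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must be in (0, 1]")


def build_contingency(rule: AssociationRule, ds: TransactionDataset) -> ContingencyTable:
    """Count the four antecedent/consequent presence cells over ``ds``.

    "Present" means the transaction contains *all* items of the side.
    """
    n11 = n10 = n01 = n00 = 0
    ant, cons = rule.antecedent, rule.consequent
    for t in ds.transactions:
        a = ant <= t
        c = cons <= t
        if a and c:
            n11 += 1
        elif a:
            n10 += 1
        elif c:
            n01 += 1
        else:
            n00 += 1
    return ContingencyTable(n11, n10, n01, n00)


def fisher_p(table: ContingencyTable, alternative: str = "greater") -> float:
    """Fisher's exact p-value for a 2x2 table.

    ``alternative="greater"`` (default) tests over-representation of the
    joint-presence cell: the hypergeometric upper tail P(X >= n11) with all
    margins fixed.  ``"two-sided"`` sums all tables at most as probable.

    Degenerate tables — N = 0 or an empty antecedent/consequent margin —
    return p = 1 (no evidence), so holdout-invisible rules rank last.
    """
    n = table.n
    if n == 0 or table.row1 == 0 or table.col1 == 0:
        return 1.0
    if alternative == "greater":
        # X ~ Hypergeom(N=n, K=col1, draws=row1); sf(k-1) = P(X >= k)
        p = float(stats.hypergeom.sf(table.n11 - 1, n, table.col1, table.row1))
    elif alternative == "two-sided":
        p = float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    # clamp: the exact p is in (0, 1]; protect against float under/overshoot
    return min(max(p, _TINY), 1.0)


def split_exploratory_holdout(
    ds: TransactionDataset, rng_seed: int, exploratory_fraction: float = 0.5
) -> tuple[TransactionDataset, TransactionDataset]:
    """Seeded shuffle split into exploratory and holdout parts.

    With the default 50/50 ratio the two sizes differ by at most one
    (exploratory takes the extra transaction on odd counts).
    """
    n = ds.n_transactions
    if n < 2:
        raise ValueError("need at least 2 transactions to split")
    if not (0.0 < exploratory_fraction < 1.0):
        raise ValueError("exploratory_fraction must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n)
    n_exp = int(math.ceil(exploratory_fraction * n))
    n_exp = min(max(n_exp, 1), n - 1)
    expl = TransactionDataset(tuple(ds.transactions[i] for i in order[:n_exp]))
    hold = TransactionDataset(tuple(ds.transactions[i] for i in order[n_exp:]))
    return expl, hold


def holdout_pvalues(
    ds: TransactionDataset,
    params: MiningParams = MiningParams(),
    rng_seed: int = 0,
    exploratory_fraction: float = 0.5,
    alternative: str = "greater",
) -> list[PValuedRule]:
    """Mine on the exploratory half, test on the holdout half.

    Returns rules sorted ascending by p-value (ties broken by the canonical
    rule key), the ranking the whole downstream method operates on.
    """
    expl, hold = split_exploratory_holdout(ds, rng_seed, exploratory_fraction)
    itemsets = mine_frequent_itemsets(expl, params.min_support, params.max_itemset_len)
    rules = generate_rules(itemsets, expl, params)
    out = [
        PValuedRule(r, fisher_p(t, alternative), t)
        for r, t in ((r, build_contingency(r, hold)) for r in rules)
    ]
    out.sort(key=lambda pr: (pr.p_value, pr.rule.key()))
    return out


def classify_by_threshold(
    ranked: Sequence[PValuedRule], threshold: float
) -> list[tuple[AssociationRule, bool]]:
    """Predict true for rules with p <= threshold, false otherwise.

    A rule whose p-value equals the threshold is called true, so a
    threshold placed exactly on an observed p-value includes that rule.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    return [(pr.rule, pr.p_value <= threshold) for pr in ranked]
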