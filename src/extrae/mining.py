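"""Frequent-itemset and association-rule mining with the five rule features.

A rule ``X -> Y`` over disjoint item sets is characterised by

* support   = supp(X ∪ Y), the fraction of transactions containing every item,
* confidence = supp(X ∪ Y) / supp(X),
* lift      = confidence / supp(Y),

plus the structural counts |X| and |Y|.  These five quantities, in this
order, are the feature vector consumed by the supervised classifier.

The miner is an Apriori-style levelwise search over vertical tid-lists.
On the corpus sizes this package targets (thousands of patients, tens to
hundreds of problem codes) it is exact and fast; its output is required to
equal brute-force power-set enumeration, which the test suite checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .transactions import TransactionDataset

__all__ = [
    "Itemset",
    "AssociationRule",
    "RuleFeatures",
    "MiningParams",
    "FEATURE_NAMES",
    "mine_frequent_itemsets",
    "generate_rules",
    "compute_features",
    "features_matrix",
    "rules_to_frame",
    "write_rules_tsv",
    "read_rules_tsv",
]

#: Fixed, documented feature order used everywhere a rule becomes a vector.
FEATURE_NAMES: tuple[str, ...] = (
    "support",
    "confidence",
    "lift",
    "n_antecedents",
    "n_consequents",
)

ITEM_SEP = "|"


@dataclass(frozen=True)
class Itemset:
    """A frequent itemset with its absolute and relative support."""

    items: frozenset[str]
    count: int
    support: float

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("itemset must be non-empty")


@dataclass(frozen=True)
class AssociationRule:
    """An implication antecedent -> consequent with its interest measures."""

    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be non-empty")
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")

    @property
    def items(self) -> frozenset[str]:
        return self.antecedent | self.consequent

    def key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """Canonical sort/identity key."""
        return (tuple(sorted(self.antecedent)), tuple(sorted(self.consequent)))

    def __str__(self) -> str:
        return (
            ITEM_SEP.join(sorted(self.antecedent))
            + " -> "
            + ITEM_SEP.join(sorted(self.consequent))
        )


@dataclass(frozen=True)
class RuleFeatures:
    support: float
    confidence: float
    lift: float
    n_antecedents: int
    n_consequents: int

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.support,
                self.confidence,
                self.lift,
                float(self.n_antecedents),
                float(self.n_consequents),
            ]
        )


@dataclass(frozen=True)
class MiningParams:
    """Thresholds and length caps applied to every emitted rule.

    Defaults are the reported mining configuration: minimum support 0.01,
    minimum confidence 0.7, minimum lift 1 (inclusive, so independence-
    boundary rules remain visible), antecedent up to 4 items, single-item
    consequent.
    """

    min_support: float = 0.01
    min_confidence: float = 0.7
    min_lift: float = 1.0
    max_antecedent_len: int = 4
    max_consequent_len: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.min_support <= 1.0):
            raise ValueError("min_support must be in (0, 1]")
        if not (0.0 < self.min_confidence <= 1.0):
            raise ValueError("min_confidence must be in (0, 1]")
        if self.min_lift < 0:
            raise ValueError("min_lift must be >= 0")
        if self.max_antecedent_len < 1 or self.max_consequent_len < 1:
            raise ValueError("length caps must be positive")

    @property
    def max_itemset_len(self) -> int:
        return self.max_antecedent_len + self.max_consequent_len


def _canonical_itemset_order(it: Itemset) -> tuple[int, tuple[str, ...]]:
    return (len(it.items), tuple(sorted(it.items)))


def mine_frequent_itemsets(
    ds: TransactionDataset,
    min_support: float,
    max_len: int | None = None,
) -> list[Itemset]:
    """Enumerate every itemset with relative support >= ``min_support``.

    Apriori over vertical tid-lists: level k candidates are joins of level
    k-1 itemsets sharing a (k-2)-prefix, counted by tid-set intersection.
    Output is in canonical order (ascending length, then lexicographic).
    """
    if not (0.0 < min_support <= 1.0):
        raise ValueError("min_support must be in (0, 1]")
    n = ds.n_transactions
    min_count = min_support * n  # compare counts, not floats-of-floats

    tids: dict[str, set[int]] = {}
    for idx, t in enumerate(ds.transactions):
        for item in t:
            tids.setdefault(item, set()).add(idx)

    out: list[Itemset] = []
    # level 1
    level: dict[tuple[str, ...], set[int]] = {
        (item,): s for item, s in tids.items() if len(s) >= min_count
    }
    k = 1
    while level:
        for key in sorted(level):
            s = level[key]
            out.append(Itemset(frozenset(key), len(s), len(s) / n))
        if max_len is not None and k >= max_len:
            break
        keys = sorted(level)
        nxt: dict[tuple[str, ...], set[int]] = {}
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break  # sorted keys: prefix mismatch ends the join block
                cand = a + (b[-1],)
                # Apriori prune: all k-subsets must be frequent
                if any(
                    cand[:j] + cand[j + 1 :] not in level for j in range(len(cand) - 1)
                ):
                    continue
                s = level[a] & level[b]
                if len(s) >= min_count:
                    nxt[cand] = s
        level = nxt
        k += 1
    return out


def generate_rules(
    itemsets: Sequence[Itemset],
    ds: TransactionDataset,
    params: MiningParams = MiningParams(),
) -> list[AssociationRule]:
    """Emit every rule meeting the support/confidence/lift and length bounds.

    For each frequent itemset Z and each bipartition Z = X ⊎ Y with
    |X| <= max_antecedent_len and 1 <= |Y| <= max_consequent_len, confidence
    and lift are computed from exact transaction counts (every subset of a
    frequent itemset is itself frequent, so its count is available).

    Returned in canonical order: descending support, then lexicographic
    antecedent and consequent.
    """
    n = ds.n_transactions
    counts = {it.items: it.count for it in itemsets}
    rules: list[AssociationRule] = []
    seen: set[tuple[frozenset[str], frozenset[str]]] = set()
    for it in itemsets:
        z = it.items
        if len(z) < 2 or len(z) > params.max_itemset_len:
            continue
        items = sorted(z)
        for y_len in range(1, min(params.max_consequent_len, len(z) - 1) + 1):
            if len(z) - y_len > params.max_antecedent_len:
                continue
            for y_items in combinations(items, y_len):
                y = frozenset(y_items)
                x = z - y
                if (x, y) in seen:
                    continue
                cx, cy = counts[x], counts[y]
                confidence = it.count / cx
                # integer products before the single division: exact where
                # the ratio is exactly representable (e.g. the 72/60 case)
                lift = (it.count * n) / (cx * cy)
                if confidence < params.min_confidence:
                    continue
                if lift < params.min_lift:  # inclusive bound
                    continue
                seen.add((x, y))
                rules.append(
                    AssociationRule(x, y, it.support, confidence, lift)
                )
    rules.sort(key=lambda r: (-r.support, r.key()))
    return rules


def compute_features(rule: AssociationRule) -> RuleFeatures:
    """The 5-component classifier feature vector, in fixed documented order."""
    return RuleFeatures(
        support=rule.support,
        confidence=rule.confidence,
        lift=rule.lift,
        n_antecedents=len(rule.antecedent),
        n_consequents=len(rule.consequent),
    )


def features_matrix(rules: Iterable[AssociationRule]) -> np.ndarray:
    """Stack rule feature vectors into an (n_rules, 5) float array."""
    rows = [compute_features(r).to_array() for r in rules]
    if not rows:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack(rows)


# --- TSV interchange ------------------------------------------------------

_BASE_COLUMNS = [
    "antecedent",
    "consequent",
    "support",
    "confidence",
    "lift",
    "n_antecedents",
    "n_consequents",
]


def rules_to_frame(
    rules: Sequence[AssociationRule],
    p_values: Sequence[float] | None = None,
    labels: Sequence[bool] | None = None,
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "antecedent": [ITEM_SEP.join(sorted(r.antecedent)) for r in rules],
            "consequent": [ITEM_SEP.join(sorted(r.consequent)) for r in rules],
            "support": [r.support for r in rules],
            "confidence": [r.confidence for r in rules],
            "lift": [r.lift for r in rules],
            "n_antecedents": [len(r.antecedent) for r in rules],
            "n_consequents": [len(r.consequent) for r in rules],
        }
    )
    if p_values is not None:
        df["p_value"] = list(p_values)
    if labels is not None:
        df["label"] = [bool(x) for x in labels]
    return df


def write_rules_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df = df.copy()
    if "p_value" in df.columns:
        df["p_value"] = df["p_value"].map(lambda p: f"{p:.6E}")
    df.to_csv(path, sep="\t", index=False)


def read_rules_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing rule columns {missing}")
    if "label" in df.columns:
        df["label"] = df["label"].astype(bool)
    return df


def rules_from_frame(df: pd.DataFrame) -> list[AssociationRule]:
    """Inverse of :func:`rules_to_frame` for the rule columns."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AssociationRule(
                frozenset(str(row.antecedent).split(ITEM_SEP)),
                frozenset(str(row.consequent).split(ITEM_SEP)),
                float(row.support),
                float(row.confidence),
                float(row.lift),
            )
        )
    return out
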