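"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — exhaustive enumeration and exact
rational arithmetic — and shares no code with the package's own paths.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import chain, combinations
from math import comb


def brute_frequent_itemsets(transactions, min_support):
    """All itemsets with support >= min_support, by power-set enumeration.

    Returns {frozenset: count}.
    """
    vocab = sorted(set().union(*transactions))
    n = len(transactions)
    out = {}
    for r in range(1, len(vocab) + 1):
        for items in combinations(vocab, r):
            s = frozenset(items)
            count = sum(1 for t in transactions if s <= t)
            if count >= min_support * n:
                out[s] = count
    return out


def brute_rules(transactions, min_support, min_confidence, min_lift,
                max_antecedent_len, max_consequent_len):
    """All rules meeting the bounds, from exhaustive bipartition of itemsets.

    Returns {(antecedent, consequent): (support, confidence, lift)} with
    frozenset keys; measures computed by direct recounting.
    """
    n = len(transactions)

    def count(s):
        return sum(1 for t in transactions if s <= t)

    freq = brute_frequent_itemsets(transactions, min_support)
    out = {}
    for z, cz in freq.items():
        if len(z) < 2 or len(z) > max_antecedent_len + max_consequent_len:
            continue
        members = sorted(z)
        subsets = chain.from_iterable(
            combinations(members, r) for r in range(1, len(members))
        )
        for y_items in subsets:
            y = frozenset(y_items)
            x = z - y
            if len(y) > max_consequent_len or len(x) > max_antecedent_len:
                continue
            cx, cy = count(x), count(y)
            confidence = cz / cx
            lift = (cz * n) / (cx * cy)
            if confidence >= min_confidence and lift >= min_lift:
                out[(x, y)] = (cz / n, confidence, lift)
    return out


def hypergeom_upper_tail(n11, n10, n01, n00) -> Fraction:
    """Exact P(X >= n11) for the 2x2 table's joint cell, fixed margins.

    X counts consequent-positives among the antecedent-present draws:
    X ~ Hypergeom(N, K=n11+n01, draws=n11+n10).
    """
    n = n11 + n10 + n01 + n00
    k_total = n11 + n01
    draws = n11 + n10
    if n == 0 or draws == 0 or k_total == 0:
        return Fraction(1)
    denom = comb(n, draws)
    num = 0
    for k in range(n11, min(draws, k_total) + 1):
        num += comb(k_total, k) * comb(n - k_total, draws - k)
    return Fraction(num, denom)


def best_cut_hits(pairs) -> int:
    """Max hits over thresholds (0 and every observed p), by linear scan.

    ``pairs`` is a sequence of (p_value, gold_label).  Prediction rule:
    true iff p <= threshold.
    """
    thresholds = {0.0} | {p for p, _ in pairs}
    best = -1
    for thr in thresholds:
        hits = sum(1 for p, lab in pairs if (p <= thr) == lab)
        best = max(best, hits)
    return best
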