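"""Seed-driven p-value threshold selection.

Given a small labeled seed of p-valued rules, choose the cutoff that
maximizes *hits*: after sorting the seed ascending by p-value, call the
first k rules true and the rest false, and count correct labels over all
cut positions k.  The optimal cut becomes the working threshold for the
unsupervised filter in the incremental loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .significance import PValuedRule

__all__ = ["ThresholdResult", "select_threshold"]


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float  # p-value cutoff; predict true iff p <= threshold
    cut_index: int  # number of seed rules classified true
    hits: int  # correct seed classifications at the optimum
    seed_accuracy: float


def _p_of(entry) -> float:
    return entry.p_value if isinstance(entry, PValuedRule) else float(entry)


def _geometric_midpoint(lo: float, hi: float) -> float:
    """Midpoint in log space; p-values span hundreds of orders of magnitude."""
    return math.exp(0.5 * (math.log(lo) + math.log(hi)))


def select_threshold(seed: Sequence[tuple[object, bool]]) -> ThresholdResult:
    """Maximize hits over all cuts of the p-sorted seed.

    ``seed`` pairs a :class:`~extrae.significance.PValuedRule` (or a bare
    p-value) with its current label.  Rules sharing one p-value form an
    atomic block — they are never split across the cut, which keeps the
    result consistent with the ``p <= threshold`` prediction rule.

    Ties in hits resolve to the smallest cut (fewest rules called true),
    the conservative choice that minimizes false positives.  The returned
    threshold is the geometric mean of the p-values flanking the cut;
    boundary cuts map to 0 (nothing true) and 1 (everything true).
    """
    if len(seed) == 0:
        raise ValueError("seed must be non-empty")
    pairs = sorted(((_p_of(p), bool(lab)) for p, lab in seed), key=lambda x: x[0])

    # collapse equal p-values into blocks
    blocks: list[tuple[float, int, int]] = []  # (p, n_true, n_rules)
    for p, lab in pairs:
        if blocks and blocks[-1][0] == p:
            bp, bt, bn = blocks[-1]
            blocks[-1] = (bp, bt + int(lab), bn + 1)
        else:
            blocks.append((p, int(lab), 1))

    total_true = sum(bt for _, bt, _ in blocks)
    n = len(pairs)

    # hits(k blocks true) = true among first k + false among the rest
    best_hits = -1
    best_k = 0
    best_cut = 0
    cum_true = 0
    cum_n = 0
    for k in range(len(blocks) + 1):
        hits = cum_true + ((n - cum_n) - (total_true - cum_true))
        if hits > best_hits:  # strict: ties keep the smaller cut
            best_hits, best_k, best_cut = hits, k, cum_n
        if k < len(blocks):
            cum_true += blocks[k][1]
            cum_n += blocks[k][2]

    if best_k == 0:
        threshold = 0.0
    elif best_k == len(blocks):
        threshold = 1.0
    else:
        lo, hi = blocks[best_k - 1][0], blocks[best_k][0]
        threshold = _geometric_midpoint(lo, hi)
        # guard rounding: the cutoff must satisfy lo <= threshold < hi
        if threshold >= hi:
            threshold = math.nextafter(hi, 0.0)
        if threshold < lo:
            threshold = lo
    return ThresholdResult(
        threshold=threshold,
        cut_index=best_cut,
        hits=best_hits,
        seed_accuracy=best_hits / n,
    )
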