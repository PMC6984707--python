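"""Combinatorics of the Alda scale's item structure.

The Alda score of lithium responsiveness combines an "A" subscale (a single
ordinal rating of overall clinical response, 0-10) with a "B" subscale of
five criteria (each scored 0-2) that discount improvement not causally
attributable to lithium.  The total score is the A rating minus the sum of
the B criteria, floored at zero.

Because high totals require a high A rating *and* near-zero B penalties,
they are reachable through far fewer item combinations than low totals:
of the 11 x 3^5 = 2673 distinct item tuples, only 79 yield a total >= 7
while 2159 yield a total <= 3.  This combinatorial funnel is the structural
reason rater agreement is tighter at the top of the scale, and it grounds
the rest of the package's asymmetric-reliability analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, Iterator

A_MAX = 10
N_B_ITEMS = 5
B_ITEM_MAX = 2
#: Number of distinct (A, B1..B5) item tuples: 11 * 3**5.
N_COMBINATIONS = (A_MAX + 1) * (B_ITEM_MAX + 1) ** N_B_ITEMS


@dataclass(frozen=True)
class ItemCombination:
    """One raw assignment of the A rating and the five B criteria."""

    a_score: int
    b_items: tuple
    total: int


def total_score(a_score: int, b_items) -> int:
    """Total Alda score for one item combination.

    ``total = max(0, A - sum(B))``: the B criteria subtract from the A
    rating, and the result is floored at zero.

    Parameters
    ----------
    a_score : int
        A-subscale rating in [0, 10].
    b_items : sequence of int
        Exactly five B-criterion scores, each in {0, 1, 2}.
    """
    if not (isinstance(a_score, (int,)) and 0 <= a_score <= A_MAX):
        raise ValueError(f"a_score must be an integer in [0, {A_MAX}], got {a_score!r}")
    b_items = tuple(b_items)
    if len(b_items) != N_B_ITEMS:
        raise ValueError(f"expected {N_B_ITEMS} B items, got {len(b_items)}")
    for b in b_items:
        if b not in (0, 1, 2):
            raise ValueError(f"B items must be in {{0, 1, 2}}, got {b!r}")
    return max(0, a_score - sum(b_items))


def enumerate_combinations() -> Iterator[ItemCombination]:
    """Yield all 2673 distinct item combinations."""
    for a in range(A_MAX + 1):
        for bs in product(range(B_ITEM_MAX + 1), repeat=N_B_ITEMS):
            yield ItemCombination(a, bs, max(0, a - sum(bs)))


def count_combinations(min_total: int, max_total: int) -> int:
    """Count item combinations whose total falls in [min_total, max_total].

    Counted over raw (A, B1..B5) tuples, not over distinct (A, sum B)
    pairs; this is the convention under which a total >= 7 is reachable in
    79 ways and a total <= 3 in 2159 ways.
    """
    if not (0 <= min_total <= max_total <= A_MAX):
        raise ValueError(
            f"require 0 <= min_total <= max_total <= {A_MAX}, "
            f"got ({min_total}, {max_total})"
        )
    return sum(1 for c in enumerate_combinations() if min_total <= c.total <= max_total)


def total_histogram() -> Dict[int, int]:
    """Number of item combinations yielding each total score 0-10."""
    hist = {t: 0 for t in range(A_MAX + 1)}
    for c in enumerate_combinations():
        hist[c.total] += 1
    return hist


def b_sum_distribution() -> Dict[int, int]:
    """Counts of B-item tuples by their sum (0-10).

    Equals the coefficients of (1 + x + x^2)^5; the counts sum to 3^5 = 243.
    """
    dist = {s: 0 for s in range(N_B_ITEMS * B_ITEM_MAX + 1)}
    for bs in product(range(B_ITEM_MAX + 1), repeat=N_B_ITEMS):
        dist[sum(bs)] += 1
    return dist


def _verify_printed_counts() -> None:
    # The max(0, A - sum B) scoring rule is pinned down by requiring that it
    # reproduce both published combination counts (79 for >=7, 2159 for <=3).
    hist = total_histogram()
    high = sum(n for t, n in hist.items() if t >= 7)
    low = sum(n for t, n in hist.items() if t <= 3)
    if (high, low) != (79, 2159):
        raise AssertionError(
            f"Alda scoring rule failed self-check: got ({high}, {low}) "
            "combinations for total>=7 / total<=3, expected (79, 2159)"
        )


_verify_printed_counts()
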