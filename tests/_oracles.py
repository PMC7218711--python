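"""Independent brute-force oracles used only by the test suite.

These enumerate the overlap nulls directly over subset configurations and
never share code with the implementation under test.
"""

from __future__ import annotations

import itertools
from math import comb


def two_way_tail_enumeration(N: int, nA: int, nB: int, k: int) -> float:
    """P(|A ∩ B| >= k) by enumerating every nB-subset against a fixed A."""
    A = frozenset(range(nA))
    hits = sum(
        1
        for B in itertools.combinations(range(N), nB)
        if len(A & frozenset(B)) >= k
    )
    return hits / comb(N, nB)


def multiway_tail_enumeration(N: int, sizes, k: int) -> float:
    """P(m-way intersection >= k) by enumerating all subset tuples.

    Exponential in the instance; intended for N <= ~8 with small sizes.
    The first set is fixed (uniformity of the null makes this WLOG).
    """
    first = frozenset(range(sizes[0]))
    others = [list(itertools.combinations(range(N), n)) for n in sizes[1:]]
    hits = total = 0
    for combo in itertools.product(*others):
        inter = first
        for s in combo:
            inter = inter & frozenset(s)
        total += 1
        hits += len(inter) >= k
    return hits / total


def fisher_combined_two(p1: float, p2: float) -> float:
    """Closed form for Fisher's method with two p-values: q(1 - ln q), q=p1*p2."""
    import math

    q = p1 * p2
    return q * (1 - math.log(q))
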