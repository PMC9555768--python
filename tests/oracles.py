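"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — enumeration and hand-rolled formulas —
kept separate from the library code they check.
"""

from itertools import combinations
from math import comb

import numpy as np


def hypergeom_tail_enumerate(q: int, m: int, N: int, k: int) -> float:
    """P(overlap >= q) by enumerating every k-subset of an N-universe.

    The first m items are the 'successes'; counts draws sharing >= q of them.
    Only feasible for tiny N.
    """
    hits = total = 0
    for draw in combinations(range(N), k):
        total += 1
        if sum(1 for i in draw if i < m) >= q:
            hits += 1
    return hits / total


def hypergeom_tail_comb(q: int, m: int, N: int, k: int) -> float:
    """P(overlap >= q) summed from the combinatorial pmf."""
    return sum(comb(m, i) * comb(N - m, k - i) for i in range(q, min(m, k) + 1)) / comb(N, k)


def bh_stepup(p_raw):
    """Benjamini-Hochberg adjusted p-values, textbook step-up recursion."""
    p = np.asarray(p_raw, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj


def mannwhitney_exact_greater(x, y) -> float:
    """One-tailed (x > y) Mann-Whitney p by enumerating all rank splits."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    observed = u_stat(x, y)
    n = len(x)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if u_stat(xs, ys) >= observed:
            hits += 1
    return hits / total
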