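"""Independent oracles shared by the enrichment and acceptance tests."""

from fractions import Fraction
from itertools import combinations
from math import comb


def tail_by_draw_enumeration(k, K, n, N):
    """Enumerate every n-subset of an N-universe and count overlaps >= k."""
    marked = set(range(K))
    hits = sum(1 for draw in combinations(range(N), n) if len(marked & set(draw)) >= k)
    return Fraction(hits, comb(N, n))


def tail_by_pmf_recurrence(k, K, n, N):
    """Exact tail via the hypergeometric pmf ratio recurrence, in rationals."""
    lo = max(0, n - (N - K))
    pmf = Fraction(comb(K, lo) * comb(N - K, n - lo), comb(N, n))
    total = pmf if lo >= k else Fraction(0)
    for j in range(lo, min(K, n)):
        pmf = pmf * (K - j) * (n - j) / ((j + 1) * (N - K - n + j + 1))
        if j + 1 >= k:
            total += pmf
    return total


def bh_step_up(p):
    """Hand implementation of the Benjamini-Hochberg step-up adjustment."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q
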