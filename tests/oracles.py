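"""Independent oracles used by the test suite.

Deliberately written with different machinery than the package: ranks come
from an explicit sort with tie-span averaging in pure Python, Pearson uses
the textbook sum formulas, and hypergeometric tails come from big-integer
binomials or exhaustive enumeration of draws.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def oracle_ranks(values):
    """Average ranks via explicit sort and tie-span scan (pure Python)."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = sum(range(i + 1, j + 2)) / (j - i + 1)
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_pearson(x, y):
    """Textbook Pearson sum formula; None on zero variance."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    if vx <= 0 or vy <= 0:
        return None
    return (n * sxy - sx * sy) / math.sqrt(vx * vy)


def oracle_spearman(x, y, min_pairs=4):
    """Pairwise-complete rank-then-Pearson, fully independent of seednet."""
    pairs = [
        (a, b)
        for a, b in zip(x, y)
        if a is not None and b is not None
        and not (isinstance(a, float) and math.isnan(a))
        and not (isinstance(b, float) and math.isnan(b))
    ]
    if len(pairs) < max(min_pairs, 2):
        return None
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    return oracle_pearson(oracle_ranks(xs), oracle_ranks(ys))


def oracle_hypergeom_upper_exact(x, n, K, N):
    """Upper tail from exact big-integer binomial coefficients."""
    hi = min(n, K)
    if x > hi:
        return Fraction(0)
    num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(max(x, 0), hi + 1))
    return Fraction(num, math.comb(N, n))


def oracle_hypergeom_tally(n, K, N):
    """Distribution of the annotated-draw count by exhaustive enumeration.

    Returns counts[x] over all C(N, n) unordered draws from a universe where
    items 0..K-1 are annotated.
    """
    counts = [0] * (n + 1)
    for draw in itertools.combinations(range(N), n):
        counts[sum(1 for i in draw if i < K)] += 1
    return counts
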