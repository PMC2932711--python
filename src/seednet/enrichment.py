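"""One-sided over-representation test: hypergeometric upper tail.

The p-value is P(X >= x) for X ~ Hypergeometric(N, K, n): the chance of
drawing at least x annotated genes when sampling n genes without
replacement from a universe of N genes of which K are annotated.  Terms are
accumulated in log space via log-gamma so the test is stable at N ~ 1e4.

Implemented from first principles on purpose: this primitive is the one
number of the pipeline that is reproducible at the desk, and it is checked
against exact big-integer enumeration in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EnrichmentResult",
    "log_choose",
    "hypergeom_upper_tail",
    "hypergeom_lower_tail",
    "overrepresentation_test",
    "benjamini_hochberg",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class EnrichmentResult:
    """Inputs and upper-tail p-value of one over-representation test."""

    term_id: str
    x: int  # observed annotated genes in the candidate list
    n: int  # candidate list size
    K: int  # annotated genes in the universe
    N: int  # universe size
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.n, self.K)):
            raise ValueError("x must satisfy 0 <= x <= min(n, K)")
        if self.n > self.N or self.K > self.N:
            raise ValueError("n and K must not exceed N")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")


def log_choose(n: int, k: int) -> float:
    """log C(n, k) via log-gamma; -inf for k outside [0, n]."""
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    if k < 0 or k > n:
        return NEG_INF
    return (
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    )


def _logsumexp(terms: list[float]) -> float:
    finite = [t for t in terms if t != NEG_INF]
    if not finite:
        return NEG_INF
    m = max(finite)
    return m + math.log(sum(math.exp(t - m) for t in finite))


def _check_params(x: int, n: int, K: int, N: int) -> None:
    if N < 0 or not (0 <= n <= N) or not (0 <= K <= N) or x < 0:
        raise ValueError(
            f"invalid hypergeometric parameters x={x}, n={n}, K={K}, N={N}"
        )


def hypergeom_upper_tail(x: int, n: int, K: int, N: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n).

    Returns exactly 1.0 when x is at or below the distribution's support
    minimum max(0, n + K - N).
    """
    _check_params(x, n, K, N)
    lo = max(0, n + K - N)
    hi = min(n, K)
    if x <= lo:
        return 1.0
    if x > hi:
        return 0.0
    denom = log_choose(N, n)
    terms = [
        log_choose(K, i) + log_choose(N - K, n - i) - denom
        for i in range(x, hi + 1)
    ]
    return min(1.0, math.exp(_logsumexp(terms)))


def hypergeom_lower_tail(x: int, n: int, K: int, N: int) -> float:
    """P(X <= x); companion used for the complement identity check."""
    _check_params(x, n, K, N)
    lo = max(0, n + K - N)
    hi = min(n, K)
    if x >= hi:
        return 1.0
    if x < lo:
        return 0.0
    denom = log_choose(N, n)
    terms = [
        log_choose(K, i) + log_choose(N - K, n - i) - denom
        for i in range(lo, x + 1)
    ]
    return min(1.0, math.exp(_logsumexp(terms)))


def overrepresentation_test(
    candidates: list[str],
    term_id: str,
    universe_size: int,
    annotated_size: int,
    annotated_genes: frozenset[str] | set[str] | None = None,
    observed: int | None = None,
) -> EnrichmentResult:
    """Upper-tail test of an annotation term within a candidate list.

    With ``annotated_genes`` supplied, x is the overlap with the candidate
    list; in counts-only mode (no membership available) the caller must
    supply ``observed``.
    """
    n = len(set(candidates))
    if n > universe_size:
        raise ValueError(
            f"candidate list ({n}) larger than universe ({universe_size})"
        )
    if annotated_genes is not None:
        x = len(set(candidates) & set(annotated_genes))
    elif observed is not None:
        x = int(observed)
    else:
        raise ValueError("counts-only mode requires an observed count x")
    p = hypergeom_upper_tail(x, n, annotated_size, universe_size)
    return EnrichmentResult(
        term_id=term_id, x=x, n=n, K=annotated_size, N=universe_size, p_value=p
    )


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """BH-adjusted q-values, same order as input.  Off by default upstream
    because the reference analysis tests a single term."""
    m = len(p_values)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p_values[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q
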