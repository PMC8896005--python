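"""Exact tail tests used by the enrichment and orthology stages.

Hypergeometric and Fisher probabilities are computed with exact integer
arithmetic (Python bignums) and converted to float once at the end, so tie
handling in the two-sided Fisher test is exact rather than
tolerance-based. The binomial tail delegates to scipy's regularized
incomplete beta, which is numerically stable for the large trial counts a
genome scan produces.
"""

from __future__ import annotations

from math import comb
from typing import Sequence, Tuple

from scipy import stats as _ss


def binomial_tail(n_in: int, n_total: int, p0: float) -> float:
    """One-sided upper binomial tail P(X >= n_in | n_total, p0)."""
    if not (0 <= n_in <= n_total):
        raise ValueError("need 0 <= n_in <= n_total")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError("p0 must be a probability")
    if n_in == 0:
        return 1.0
    return float(_ss.binom.sf(n_in - 1, n_total, p0))


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric P(X >= k | N, K, n), exact summation.

    N objects, K marked, n drawn without replacement.
    """
    if N <= 0:
        raise ValueError("population size N must be positive")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    if k <= max(0, K + n - N):
        return 1.0
    hi = min(K, n)
    if k > hi:
        return 0.0
    num = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, hi + 1))
    return num / comb(N, n)


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> Tuple[float, bool]:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    Sums the probabilities of all outcomes (at fixed margins) no more
    likely than the observed one; comparisons use exact integer weights so
    ties are handled exactly. Returns ``(p, degenerate)`` where degenerate
    flags an all-zero row or column margin (p is 1 there by convention).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0, True
    n = r1 + r2
    lo, hi = max(0, r1 - c2), min(r1, c1)
    # integer weights proportional to the hypergeometric pmf at fixed margins
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w <= w_obs)
    return num / comb(n, c1), False
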