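"""Exact hypergeometric upper tail shared by the sponge test and enrichment.

Both the ceRNA sponge-overlap test and gene-set over-representation reduce to
the same quantity: for a universe of N items of which K are "marked", and a
draw of n items, the probability of seeing at least x marked items,

    P[X >= x] = sum_{i=x}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n).

The tail is computed in exact integer arithmetic so that it agrees with an
exhaustive enumeration of all C(N, n) draws as a rational number, not merely
to float precision.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

__all__ = ["hypergeom_upper_tail", "hypergeom_upper_tail_exact"]


def _check(x: int, N: int, K: int, n: int) -> None:
    for name, v in (("x", x), ("N", N), ("K", K), ("n", n)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if K > N or n > N:
        raise ValueError(f"inconsistent counts: K={K}, n={n} exceed universe N={N}")
    if x > min(K, n):
        raise ValueError(f"overlap x={x} exceeds min(K={K}, n={n})")


def hypergeom_upper_tail_exact(x: int, N: int, K: int, n: int) -> Fraction:
    """Exact P[X >= x] for X ~ Hypergeometric(N, K, n) as a Fraction."""
    _check(x, N, K, n)
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(x, min(K, n) + 1))
    return Fraction(num, comb(N, n))


def hypergeom_upper_tail(x: int, N: int, K: int, n: int) -> float:
    """P[X >= x] for X ~ Hypergeometric(N, K, n), as a float.

    ``x = 0`` gives 1.0 (the certain event).
    """
    return float(hypergeom_upper_tail_exact(x, N, K, n))
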