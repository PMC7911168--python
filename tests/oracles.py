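"""Independent brute-force oracles used by the test suite.

These are deliberately naive (exact rational enumeration, plain Python
loops) and share no code with the implementation paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational enumeration over the support."""
    N, K, n = a + b + c + d, a + b, a + c
    if K == 0 or c + d == 0 or n == 0 or b + d == 0:
        return 1.0
    denom = comb(N, n)
    observed = Fraction(comb(K, a) * comb(N - K, n - a), denom)
    total = Fraction(0)
    for k in range(max(0, n - (N - K)), min(K, n) + 1):
        pk = Fraction(comb(K, k) * comb(N - K, n - k), denom)
        if pk <= observed * (1 + Fraction(1, 10**7)):
            total += pk
    return float(min(total, Fraction(1)))


def fst_ratio_of_sums_arithmetic(pairs: list[tuple[float, float]]) -> float:
    """Ratio-of-sums Wright/Nei FST by direct arithmetic on frequency pairs."""
    num = den = 0.0
    for p1, p2 in pairs:
        s = p1 + p2
        if s == 0.0 or s == 2.0:
            continue
        pbar = s / 2.0
        ht = 2.0 * pbar * (1.0 - pbar)
        hs = (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2)) / 2.0
        num += ht - hs
        den += ht
    return num / den
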