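"""Independent brute-force oracles for the ranked-list enrichment test.

Everything here is exact rational arithmetic built from first principles
(counting label placements), deliberately sharing no code with the package
implementation it checks.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


def tail_fraction(b: int, n: int, B: int, N: int) -> Fraction:
    """P(X >= b) for a hypergeometric draw, as an exact rational."""
    total = comb(N, n)
    acc = 0
    for k in range(b, min(n, B) + 1):
        acc += comb(B, k) * comb(N - B, n - k)
    return Fraction(acc, total)


def min_tail_fraction(positions: tuple[int, ...], N: int, B: int) -> Fraction:
    """Exact minimum prefix tail over n = 1..N-1 for labels at the given
    0-based positions."""
    best = Fraction(1)
    ones = 0
    pos = set(positions)
    for n in range(1, N):
        if (n - 1) in pos:
            ones += 1
        t = tail_fraction(ones, n, B, N)
        if t < best:
            best = t
    return best


def enumerate_null(N: int, B: int) -> list[Fraction]:
    """Exact minimum-tail statistic of every C(N, B) label placement."""
    return [
        min_tail_fraction(pos, N, B) for pos in combinations(range(N), B)
    ]


def exhaustive_pvalue(stat: float, N: int, B: int) -> float:
    """P(min-tail <= stat) by complete enumeration of placements."""
    stats = enumerate_null(N, B)
    thr = stat * (1 + 1e-9)
    return sum(s <= thr for s in stats) / comb(N, B)
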