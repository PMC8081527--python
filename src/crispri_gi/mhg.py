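"""Exact minimum-hypergeometric (mHG) test for ranked binary lists.

Given N ranked items of which B carry a label (the guides of one gene), the
mHG statistic is the minimum, over list prefixes of length n = 1..N−1, of
the hypergeometric tail probability of observing at least the labels seen in
that prefix.  Because the minimum is taken over all prefixes, the statistic
itself is not a p-value; the exact p-value is the null probability — over
the uniform placement of the B labels among the N ranks — that the minimum
is at least as small as observed.

The exact p-value is computed by a path-count dynamic programme on the
(ranks seen, labels seen) lattice.  A placement of labels is a monotone
lattice path from (0,0) to (N,B); the rejection region R(s) = {(n,b):
tail(b; n) ≤ s, 1 ≤ n ≤ N−1} is upward-closed in b and, for fixed b,
a contiguous range of small n, so a path can only enter R through its lower
staircase boundary via a label step.  Counting paths with exact integer
arithmetic and accumulating first-entry mass gives

    p = Σ_entry  paths_avoiding_R(entry − 1) · C(N−n, B−b) / C(N, B)

with no underflow or cancellation at any list size used here.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy.stats import hypergeom

from .errors import CrisprGiError, ResourceError

# relative slack when testing "tail ≤ stat": the statistic and the region are
# evaluated with the same routine, so ties must compare equal despite fp noise
_REL_TOL = 1e-12

DEFAULT_MAX_CELLS = 50_000_000


def hypergeometric_tail(b: int, n: int, B: int, N: int) -> float:
    """P(X ≥ b) for X ~ Hypergeometric(N population, B successes, n drawn)."""
    if not (0 <= b <= min(n, B) and 0 <= n <= N and 0 <= B <= N):
        raise CrisprGiError(
            f"invalid hypergeometric tail arguments b={b}, n={n}, B={B}, N={N}"
        )
    if b == 0:
        return 1.0
    return float(hypergeom.sf(b - 1, N, B, n))


def mhg_statistic(labels) -> tuple[float, int]:
    """Minimum hypergeometric tail over prefixes of a ranked 0/1 list.

    Returns ``(stat, pivot)`` where pivot is the smallest prefix length
    attaining the minimum (0 when no prefix exists, i.e. N == 1).  The
    prefix n = N is excluded (its tail is always 1) and the statistic is
    capped at 1.
    """
    lab = np.asarray(labels)
    if lab.ndim != 1 or len(lab) < 1:
        raise CrisprGiError("labels must be a nonempty 1-d 0/1 vector")
    lab = lab.astype(bool)
    N = len(lab)
    B = int(lab.sum())
    if B == 0:
        raise CrisprGiError("labels contain no ones: gene has no guides in list")
    if N == 1:
        return 1.0, 0
    n = np.arange(1, N)
    b = np.cumsum(lab)[: N - 1]
    tails = hypergeom.sf(b - 1, N, B, n)
    i = int(np.argmin(tails))
    return min(float(tails[i]), 1.0), i + 1


@lru_cache(maxsize=8)
def _prefix_tail_table(N: int, B: int) -> np.ndarray:
    """tails[b-1, n-1] = P(X ≥ b | prefix n) for b = 1..B, n = 1..N−1.

    Each row is nondecreasing in n (0 while n < b, then increasing), which
    lets region bounds be read off by binary search.  Cached because every
    gene of a screen shares N and, typically, B.
    """
    ks = np.arange(1, B + 1)
    return hypergeom.sf(ks[:, None] - 1, N, B, np.arange(1, N)[None, :])


def _region_bounds(stat: float, N: int, B: int) -> np.ndarray:
    """For b = 1..B, the largest prefix length n ≤ N−1 with
    tail(b; n) ≤ stat.  The tail is increasing in n at fixed b and
    decreasing in b at fixed n, so these bounds are nondecreasing in b and
    fully describe the upward-closed rejection region.  (Bounds may cover
    unreachable cells with b > n, where the tail is 0; the DP never holds
    mass there, so they are harmless.)"""
    thr = stat * (1.0 + _REL_TOL)
    table = _prefix_tail_table(N, B)
    n_hi = np.zeros(B + 1, dtype=np.int64)
    for b in range(1, B + 1):
        n_hi[b] = np.searchsorted(table[b - 1], thr, side="right")
    return n_hi


def mhg_exact_pvalue(
    stat: float, N: int, B: int, max_cells: int = DEFAULT_MAX_CELLS
) -> float:
    """Exact null probability that the mHG statistic is ≤ ``stat``.

    Uniform null: the B labels occupy a uniformly random B-subset of the N
    ranks.  Exact integer path-count DP (see module docstring); raises
    :class:`ResourceError` when the N × (B+1) lattice exceeds ``max_cells``
    (use :func:`permutation_pvalue` instead at that scale).
    """
    if not 0 < B <= N:
        raise CrisprGiError(f"need 0 < B ≤ N, got B={B}, N={N}")
    if not 0.0 < stat:
        raise CrisprGiError("stat must be positive")
    if stat >= 1.0:
        return 1.0
    if N * (B + 1) > max_cells:
        raise ResourceError(
            f"exact mHG lattice {N}×{B + 1} exceeds budget {max_cells}; "
            "use permutation_pvalue instead"
        )

    n_hi = _region_bounds(stat, N, B)
    nmax = int(n_hi.max())
    if nmax == 0:
        return 0.0  # stat below the smallest achievable tail
    # bc(n) = least b whose region covers prefix n; nondecreasing in n
    bc_of = np.searchsorted(n_hi[1:], np.arange(1, nmax + 1), side="left") + 1

    W = [0] * (B + 1)  # paths to (n, b) that never touched the region
    W[0] = 1
    hit = 0  # Σ first-entry paths × free completions
    for n in range(1, nmax + 1):
        for b in range(min(B, n), 0, -1):
            W[b] += W[b - 1]
        bc = int(bc_of[n - 1])
        if bc <= B and W[bc]:
            hit += W[bc] * math.comb(N - n, B - bc)
            W[bc] = 0
    return float(Fraction(hit, math.comb(N, B)))


def permutation_pvalue(
    labels, n_perm: int, seed: int
) -> tuple[float, float]:
    """Monte-Carlo p-value for the mHG statistic, with its standard error.

    Draws ``n_perm`` uniform placements of the labels, applies the add-one
    correction p = (1 + #{mHG_perm ≤ mHG_obs}) / (n_perm + 1), and returns
    the binomial standard error of the estimate.  Fully reproducible from
    ``seed``.
    """
    if n_perm < 1:
        raise CrisprGiError("n_perm must be ≥ 1")
    lab = np.asarray(labels).astype(bool)
    N = len(lab)
    B = int(lab.sum())
    obs, _ = mhg_statistic(lab)
    thr = obs * (1.0 + _REL_TOL)

    # tails[k-1, n-1] = P(X ≥ k | prefix n); evaluated only at label steps
    ks = np.arange(1, B + 1)
    tail_table = hypergeom.sf(
        ks[:, None] - 1, N, B, np.arange(1, N + 1)[None, :]
    )

    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, int(4_000_000 // max(N, 1)))
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        r = rng.random((c, N))
        pos = np.sort(np.argpartition(r, B - 1, axis=1)[:, :B], axis=1)
        stats = tail_table[ks - 1, pos].min(axis=1)
        hits += int((stats <= thr).sum())
        done += c
    p = (1 + hits) / (n_perm + 1)
    se = math.sqrt(p * (1 - p) / n_perm)
    return p, se
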