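"""Counting distinct ROC curves per AUC value.

With n TPs and m TNs every tie-free interleaving of the scores maps to a
monotone staircase from (0,0) to (1,1); the AUC deficit i = nm·(1 − AUC)
equals the number of unit rectangles of area 1/nm missing above the curve.
The number of distinct ROC curves with deficit i, written k_i, equals the
number of integer partitions of i into at most n parts, each part at most
m — equivalently the coefficient of q^i in the Gaussian binomial
coefficient [n+m, n]_q.

The partition ↔ curve correspondence: writing the pooled scores in
increasing order, let a_j be the number of TNs below the j-th smallest TP;
the multiset {m − a_j} (zeros dropped, sorted decreasingly) is the
partition, and the deficit is its sum.

Counts grow past 64-bit range quickly (a 50×50 box holds ~1e28 partitions
near the centre), so everything here uses Python's arbitrary-precision
integers, and null probabilities are formed as exact rationals before any
float conversion.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from fractions import Fraction
from math import comb, factorial

import pandas as pd

__all__ = [
    "CountTable",
    "count_roc_curves",
    "count_table",
    "mann_whitney_null",
]


@dataclass(frozen=True)
class CountTable:
    """Counts k_0..k_imax of distinct ROC curves per AUC deficit."""

    n: int
    m: int
    counts: tuple

    @property
    def i_max(self) -> int:
        return len(self.counts) - 1

    def __getitem__(self, i: int) -> int:
        return self.counts[i]

    def to_frame(self) -> pd.DataFrame:
        nm = self.n * self.m
        return pd.DataFrame({
            "deficit": range(len(self.counts)),
            "auc": [f"{nm - i}/{nm}" for i in range(len(self.counts))],
            "k": [str(k) for k in self.counts],
        })


def _validate(i: int, n: int, m: int) -> None:
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    if i < 0 or i > n * m:
        raise ValueError(f"deficit i={i} outside [0, nm={n * m}]")


def _recurse(x: int, max_part: int, max_parts: int, memo: dict) -> int:
    """Number of partitions of x into at most ``max_parts`` parts, each at
    most ``max_part``.

    Termination mirrors the defining decomposition (u·v) = (u·v−1) +
    (u−v·v): either no part of the current maximal size is used, or one is
    removed, spending one of the available parts.
    """
    if x < 0 or max_parts < 0:
        return 0
    if max_part == 1:
        return 1 if x <= max_parts else 0
    if x == 0:
        return 1
    key = (x, max_part, max_parts)
    hit = memo.get(key)
    if hit is not None:
        return hit
    val = (_recurse(x, max_part - 1, max_parts, memo)
           + _recurse(x - max_part, max_part, max_parts - 1, memo))
    memo[key] = val
    return val


def count_roc_curves(i: int, n: int, m: int, memo: dict | None = None) -> int:
    """Number k_i of distinct ROC curves with AUC deficit ``i``.

    Equals the number of partitions of ``i`` into at most ``n`` parts, each
    part at most ``m``.  Memoised; for deficits in the thousands prefer
    :func:`count_table`, which is an iterative dynamic program.
    """
    _validate(i, n, m)
    if memo is None:
        memo = _recurse.__dict__.setdefault("shared_memo", {})
    depth_needed = 2 * (i + n + m) + 100
    if sys.getrecursionlimit() < depth_needed:
        sys.setrecursionlimit(depth_needed)
    return _recurse(i, m, n, memo)


def count_table(n: int, m: int, i_max: int | None = None) -> CountTable:
    """Table of counts k_0..k_imax by iterative dynamic programming.

    Uses the box-partition recurrence over the maximal allowed part: a
    partition either omits parts of size ``s`` (box n×(s−1)) or contains
    one (remove it: box (n−1)×s, deficit reduced by s).  Cost is
    O(n·m·i_max) big-int additions, no recursion depth issues.
    """
    if i_max is None:
        i_max = n * m
    _validate(i_max, n, m)
    width = i_max + 1
    # N(j, s)[d] = partitions of d into at most j parts, each part <= s,
    # via N(j, s) = N(j, s-1) + shift_s N(j-1, s); only the previous j-layer
    # is kept.  prev[s] is N(j-1, s); cur[s] becomes N(j, s).
    prev = [[1] + [0] * i_max for _ in range(m + 1)]  # j = 0
    for _j in range(1, n + 1):
        cur = [[1] + [0] * i_max]  # s = 0
        for s in range(1, m + 1):
            no_s = cur[s - 1]
            use_s = prev[s]
            row = [no_s[d] + (use_s[d - s] if d >= s else 0)
                   for d in range(width)]
            cur.append(row)
        prev = cur
    return CountTable(n=n, m=m, counts=tuple(prev[m]))


def mann_whitney_null(n: int, m: int, i_max: int | None = None) -> list[float]:
    """Exact null distribution of the AUC deficit when F = G.

    Every one of the binomial(n+m, n) interleavings is equally likely, with
    probability n!m!/(n+m)!, so P(deficit = i) = k_i · n!m!/(n+m)!.  The
    probabilities are formed as exact rationals and converted to floats at
    the end.
    """
    table = count_table(n, m, i_max)
    base = Fraction(factorial(n) * factorial(m), factorial(n + m))
    return [float(k * base) for k in table.counts]


def mann_whitney_null_exact(n: int, m: int,
                            i_max: int | None = None) -> list[Fraction]:
    """As :func:`mann_whitney_null` but returning exact rationals."""
    table = count_table(n, m, i_max)
    base = Fraction(factorial(n) * factorial(m), factorial(n + m))
    return [k * base for k in table.counts]
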