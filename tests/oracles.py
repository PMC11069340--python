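"""Independent brute-force oracles used by the test suite.

These are deliberately naive implementations, kept separate from the
package code paths they check.
"""

from __future__ import annotations

import math
from fractions import Fraction

from Bio.Align import substitution_matrices

NEG_INF = float("-inf")


def gotoh_score(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> float:
    """Affine-gap global alignment score by an explicit three-state DP.

    A gap of length L costs gap_open + gap_extend * L; end gaps are
    penalized.  Only the score is computed (no traceback).
    """
    sub = substitution_matrices.load(matrix_name)
    open_cost = gap_open + gap_extend  # first gap column
    n, m = len(a), len(b)
    # M: last column is a match/mismatch; X: gap in b (a-residue over gap);
    # Y: gap in a.
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best_prev + s
            X[i][j] = max(M[i - 1][j] - open_cost, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - open_cost)
            Y[i][j] = max(M[i][j - 1] - open_cost, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - open_cost)
    return max(M[n][m], X[n][m], Y[n][m])


def fisher_two_sided_exact(table: list[list[int]]) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration in exact rationals."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r, k = a + b, a + c
    denom = math.comb(n, k)

    def pmf(x: int) -> Fraction:
        return Fraction(math.comb(r, x) * math.comb(n - r, k - x), denom)

    lo, hi = max(0, k - (n - r)), min(r, k)
    p_obs = pmf(a)
    return sum((pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs), Fraction(0))


def welch_p_from_betainc(t: float, df: float) -> float:
    """Two-sided Student-t tail via the regularized incomplete beta."""
    from scipy.special import betainc

    return float(betainc(df / 2.0, 0.5, df / (df + t * t)))
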