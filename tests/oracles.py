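"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: plain-Python Gotoh
dynamic programming for global/local affine-gap alignment, a quadratic
ECDF scan for the two-sample KS statistic, and the Benjamini-Hochberg
step-up formula evaluated directly.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

GAP_OPEN = 11  # a gap of length k costs GAP_OPEN + k * GAP_EXTEND
GAP_EXTEND = 1

NEG = float("-inf")


def _score(x: str, y: str) -> float:
    return float(_B62[x, y])


def global_align_score(a: str, b: str) -> float:
    """Needleman-Wunsch with affine gaps, end gaps penalized (Gotoh)."""
    n, m = len(a), len(b)
    first = GAP_OPEN + GAP_EXTEND  # opening residue of a gap
    M = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in residue pair
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(first + (i - 1) * GAP_EXTEND)
    for j in range(1, m + 1):
        Y[0][j] = -(first + (j - 1) * GAP_EXTEND)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _score(a[i - 1], b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - GAP_EXTEND, Y[i - 1][j] - first)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - GAP_EXTEND, X[i][j - 1] - first)
    return max(M[n][m], X[n][m], Y[n][m])


def local_align_score(a: str, b: str) -> float:
    """Smith-Waterman with affine gaps (raw score, >= 0)."""
    n, m = len(a), len(b)
    first = GAP_OPEN + GAP_EXTEND
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - GAP_EXTEND)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - GAP_EXTEND)
            H[i][j] = max(
                0.0, H[i - 1][j - 1] + _score(a[i - 1], b[j - 1]), E[i][j], F[i][j]
            )
            best = max(best, H[i][j])
    return best


def local_bit_score(a: str, b: str, lam: float = 0.267, k: float = 0.041) -> float:
    raw = local_align_score(a, b)
    if raw <= 0:
        return 0.0
    return (lam * raw - math.log(k)) / math.log(2)


def ks_statistic(x, y) -> float:
    """Exact sup over pooled points of |ECDF_x - ECDF_y| (quadratic)."""
    pooled = sorted(list(x) + list(y))
    best = 0.0
    for t in pooled:
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best


def bh_stepup(pvalues):
    """Direct evaluation of q_(i) = min_{j>=i} p_(j) * m / j in input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q
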