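"""Independent brute-force oracles for alignment scores.

These are deliberately naive memoized recursions, kept separate from the
package so that the production dynamic programs are checked against an
independent derivation of the same recurrences.
"""

from __future__ import annotations

from functools import lru_cache

NEG = float("-inf")


def sw_affine_score(a: str, b: str, matrix, open_gap: float, extend_gap: float) -> float:
    """Optimal local (Smith-Waterman) affine-gap score by plain recursion.

    Gap of length k costs open_gap + (k-1)*extend_gap (both negative).
    """

    @lru_cache(maxsize=None)
    def M(i: int, j: int) -> float:
        if i == 0 or j == 0:
            return NEG
        best_prev = max(0.0, M(i - 1, j - 1), X(i - 1, j - 1), Y(i - 1, j - 1))
        return best_prev + float(matrix[a[i - 1], b[j - 1]])

    @lru_cache(maxsize=None)
    def X(i: int, j: int) -> float:  # gap in b: consumes a[i-1]
        if i == 0:
            return NEG
        return max(M(i - 1, j) + open_gap, X(i - 1, j) + extend_gap, Y(i - 1, j) + open_gap)

    @lru_cache(maxsize=None)
    def Y(i: int, j: int) -> float:  # gap in a: consumes b[j-1]
        if j == 0:
            return NEG
        return max(M(i, j - 1) + open_gap, X(i, j - 1) + open_gap, Y(i, j - 1) + extend_gap)

    best = 0.0
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            best = max(best, M(i, j))
    return best


def global_affine_score(S, open_gap: float, extend_gap: float) -> float:
    """Optimal global affine-gap score over a column-score matrix by recursion.

    ``S[i][j]`` is the score of aligning position i of the first profile to
    position j of the second; gap of length k costs open + (k-1)*extend
    (penalties given positive).
    """
    n = len(S)
    m = len(S[0]) if n else 0
    go, ge = open_gap, extend_gap

    @lru_cache(maxsize=None)
    def M(i: int, j: int) -> float:
        if i == 0 and j == 0:
            return 0.0
        if i == 0 or j == 0:
            return NEG
        prev = max(M(i - 1, j - 1), X(i - 1, j - 1), Y(i - 1, j - 1))
        return prev + float(S[i - 1][j - 1]) if prev > NEG else NEG

    @lru_cache(maxsize=None)
    def X(i: int, j: int) -> float:  # gap in the second profile
        if i == 0:
            return NEG
        if j == 0:
            return -go - (i - 1) * ge
        return max(M(i - 1, j) - go, X(i - 1, j) - ge, Y(i - 1, j) - go)

    @lru_cache(maxsize=None)
    def Y(i: int, j: int) -> float:  # gap in the first profile
        if j == 0:
            return NEG
        if i == 0:
            return -go - (j - 1) * ge
        return max(M(i, j - 1) - go, X(i, j - 1) - go, Y(i, j - 1) - ge)

    return max(M(n, m), X(n, m), Y(n, m))


def hamming_identity(a: str, b: str) -> float:
    """Identity of two equal-length sequences where no gap is favourable."""
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)
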