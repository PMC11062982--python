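"""Independent reference computations used to pin expected test values.

Each oracle is deliberately written in the most transparent way available
(explicit recursion, sorting, all-pairs loops) and shares no code with the
implementations it checks.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

NEG = float("-inf")


def brute_local_score(
    query: str,
    ref: str,
    match: int = 2,
    mismatch: int = 3,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> int:
    """Optimal affine-gap local alignment score by memoized recursion.

    Defined directly from the alignment-ending-state recurrences (an
    alignment ends with a match/mismatch column, a gap column in the query,
    or a gap column in the reference); intended for tiny instances only.
    'N' never matches anything.
    """
    q, r = query.upper(), ref.upper()

    def s(i: int, j: int) -> int:
        a, b = q[i - 1], r[j - 1]
        return match if (a == b and a != "N") else -mismatch

    @lru_cache(maxsize=None)
    def M(i: int, j: int) -> float:  # ends with q[i] aligned to r[j]
        if i < 1 or j < 1:
            return NEG
        return s(i, j) + max(0.0, M(i - 1, j - 1), X(i - 1, j - 1), Y(i - 1, j - 1))

    @lru_cache(maxsize=None)
    def X(i: int, j: int) -> float:  # ends consuming r[j] in a gap
        if j < 1:
            return NEG
        return max(M(i, j - 1) - gap_open - gap_extend, X(i, j - 1) - gap_extend)

    @lru_cache(maxsize=None)
    def Y(i: int, j: int) -> float:  # ends consuming q[i] in a gap
        if i < 1:
            return NEG
        return max(M(i - 1, j) - gap_open - gap_extend, Y(i - 1, j) - gap_extend)

    best = 0.0
    for i in range(1, len(q) + 1):
        for j in range(1, len(r) + 1):
            best = max(best, M(i, j))  # optimal local ends in a match column
    return int(best)


def brute_percentile_ranks(column: list[float]) -> list[float]:
    """Average-rank percentile of each value, by explicit pairwise counting."""
    n = len(column)
    out = []
    for x in column:
        below = sum(1 for y in column if y < x)
        equal = sum(1 for y in column if y == x)
        avg_rank = below + (equal + 1) / 2
        out.append(avg_rank / n * 100.0)
    return out


def brute_top_neighbors(matrix: np.ndarray, genes: list[str], focal: str,
                        k: int) -> list[tuple[str, float]]:
    """Top-k Pearson neighbors by all-pairs np.corrcoef, ties by gene id."""
    fi = genes.index(focal)
    scored = []
    for i, g in enumerate(genes):
        if i == fi:
            continue
        if np.std(matrix[i]) == 0 or np.std(matrix[fi]) == 0:
            continue
        r = float(np.corrcoef(matrix[fi], matrix[i])[0, 1])
        scored.append((g, r))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:k]
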