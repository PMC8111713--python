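"""Independent reference implementations used to validate the package.

These deliberately use the simplest possible algorithms (exhaustive dynamic
programming, exhaustive enumeration) and share no code with the package.
"""

from __future__ import annotations

import itertools
import math


def semiglobal_score_oracle(
    read: str,
    ref: str,
    match: int = 2,
    mismatch: int = -4,
    gap_open: int = -4,
    gap_extend: int = -1,
) -> float:
    """Unbanded affine-gap semi-global alignment score (read global,
    reference overhangs free), by plain dynamic programming."""
    NEG = -math.inf
    m, n = len(read), len(ref)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        M[0][j] = 0.0
    for i in range(1, m + 1):
        X[i][0] = gap_open + gap_extend * i
        for j in range(1, n + 1):
            s = match if read[i - 1] == ref[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                max(M[i - 1][j], Y[i - 1][j]) + gap_open + gap_extend,
                X[i - 1][j] + gap_extend,
            )
            Y[i][j] = max(
                max(M[i][j - 1], X[i][j - 1]) + gap_open + gap_extend,
                Y[i][j - 1] + gap_extend,
            )
    return max(max(M[m][j], X[m][j], Y[m][j]) for j in range(n + 1))


def best_pairing_oracle(similarity: dict[tuple[str, str], float]) -> dict[str, str]:
    """Optimal one-to-one assignment by exhaustive enumeration of all
    pairings."""
    lefts = sorted({a for a, _ in similarity})
    rights = sorted({b for _, b in similarity})
    assert len(lefts) == len(rights)
    best, best_total = None, -math.inf
    for perm in itertools.permutations(rights):
        total = sum(similarity[(a, b)] for a, b in zip(lefts, perm))
        if total > best_total:
            best, best_total = dict(zip(lefts, perm)), total
    return best
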