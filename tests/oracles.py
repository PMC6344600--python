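"""Independent reference implementations used only by the tests.

These deliberately share no code with the package: the motif oracle is
a plain exhaustive window loop, and the alignment oracle is a textbook
Gotoh dynamic-programming recursion.
"""

from __future__ import annotations


def brute_motif_positions(seq: str, spacers=(2,)) -> tuple[int, ...]:
    """Check every start index for C-X{k}-C-H by direct indexing."""
    found = set()
    for k in spacers:
        width = k + 3
        for i in range(len(seq) - width + 1):
            if seq[i] == "C" and seq[i + k + 1] == "C" and seq[i + k + 2] == "H":
                found.add(i)
    return tuple(sorted(found))


def gotoh_local_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Smith-Waterman with affine gaps; a gap of length L costs
    ``gap_open + (L-1) * gap_extend``.  Returns the optimal local score."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]   # match/mismatch state
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(
                0.0,
                max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s,
            )
            X[i][j] = max(
                M[i - 1][j] - gap_open,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - gap_open,
            )
            if M[i][j] > best:
                best = M[i][j]
    return best
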