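"""Independent brute-force affine-gap global alignment oracle for tests.

A straightforward three-state dynamic program with full co-optimal traceback
enumeration, written without reference to the package's alignment path. Gap
runs cost open + (length - 1) * extend. Intended for short sequences only.
"""

from __future__ import annotations

NEG = float("-inf")


def _score(a: str, b: str, match: float, mismatch: float) -> float:
    return match if a == b else mismatch


def affine_dp(
    ref: str,
    read: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
):
    """Return (best_score, M, X, Y) score tables.

    M[i][j]: best score of aligning ref[:i] / read[:j] ending in a match column.
    X[i][j]: ... ending with a gap in the read (deletion of ref base i).
    Y[i][j]: ... ending with a gap in the ref (insertion of read base j).
    """
    n, m = len(ref), len(read)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                M[i][j] = _score(ref[i - 1], read[j - 1], match, mismatch) + max(
                    M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]
                )
            if i > 0 and not (i > 0 and j == 0):
                X[i][j] = max(
                    X[i][j],
                    M[i - 1][j] + gap_open,
                    X[i - 1][j] + gap_extend,
                    Y[i - 1][j] + gap_open,
                )
            if j > 0 and not (j > 0 and i == 0):
                Y[i][j] = max(
                    Y[i][j],
                    M[i][j - 1] + gap_open,
                    Y[i][j - 1] + gap_extend,
                    X[i][j - 1] + gap_open,
                )
    best = max(M[n][m], X[n][m], Y[n][m])
    return best, M, X, Y


def optimal_score(ref: str, read: str, **scoring) -> float:
    return affine_dp(ref, read, **scoring)[0]


def all_optimal_alignments(ref: str, read: str, **scoring) -> set[tuple[str, str]]:
    """Every co-optimal (ref_row, read_row) pair, by exhaustive traceback."""
    best, M, X, Y = affine_dp(ref, read, **scoring)
    match = scoring.get("match", 1.0)
    mismatch = scoring.get("mismatch", -2.0)
    gap_open = scoring.get("gap_open", -4.0)
    gap_extend = scoring.get("gap_extend", -1.0)
    out: set[tuple[str, str]] = set()
    eps = 1e-9

    def walk(i: int, j: int, state: str, rows: tuple[str, str]) -> None:
        if i == 0 and j == 0:
            if state == "M":
                out.add(rows)
            return
        if state == "M":
            if i == 0 or j == 0:
                return
            s = M[i][j] - _score(ref[i - 1], read[j - 1], match, mismatch)
            col = (ref[i - 1] + rows[0], read[j - 1] + rows[1])
            for prev, tab in (("M", M), ("X", X), ("Y", Y)):
                if abs(tab[i - 1][j - 1] - s) < eps:
                    walk(i - 1, j - 1, prev, col)
        elif state == "X":
            if i == 0:
                return
            col = (ref[i - 1] + rows[0], "-" + rows[1])
            if abs(M[i - 1][j] + gap_open - X[i][j]) < eps:
                walk(i - 1, j, "M", col)
            if abs(X[i - 1][j] + gap_extend - X[i][j]) < eps:
                walk(i - 1, j, "X", col)
            if abs(Y[i - 1][j] + gap_open - X[i][j]) < eps:
                walk(i - 1, j, "Y", col)
        else:  # Y
            if j == 0:
                return
            col = ("-" + rows[0], read[j - 1] + rows[1])
            if abs(M[i][j - 1] + gap_open - Y[i][j]) < eps:
                walk(i, j - 1, "M", col)
            if abs(Y[i][j - 1] + gap_extend - Y[i][j]) < eps:
                walk(i, j - 1, "Y", col)
            if abs(X[i][j - 1] + gap_open - Y[i][j]) < eps:
                walk(i, j - 1, "X", col)

    n, m = len(ref), len(read)
    for state, tab in (("M", M), ("X", X), ("Y", Y)):
        if abs(tab[n][m] - best) < eps:
            walk(n, m, state, ("", ""))
    return out
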