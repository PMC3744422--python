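"""Independent quadratic-time local-alignment oracle for the test suite.

A deliberately plain, full-matrix affine-gap Smith-Waterman written
separately from the package's alignment engine, used to verify the
engine's identity/coverage/score on small instances.  It implements the
same documented conventions: match +2 / mismatch -3 / gap open -5 (first
gap base) / gap extend -2, `N` never matches, the end cell is the first
maximum in row-major order, and the traceback prefers diagonal moves,
then query-consuming gaps, then target-consuming gaps (closing a gap as
soon as the open-score path explains it).
"""

from dataclasses import dataclass

NEG = -10 ** 8


@dataclass
class OracleAlignment:
    score: int
    identity: float
    coverage: float
    q_start: int
    q_end: int


def smith_waterman(query: str, target: str, match: int = 2,
                   mismatch: int = -3, gap_open: int = -5,
                   gap_extend: int = -2) -> OracleAlignment:
    q = query.upper()
    t = target.upper()
    n, m = len(q), len(t)

    def sub(a: str, b: str) -> int:
        if a == b and a in "ACGT":
            return match
        return mismatch

    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open)
            h = max(0, H[i - 1][j - 1] + sub(q[i - 1], t[j - 1]),
                    E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return OracleAlignment(score=0, identity=0.0, coverage=0.0,
                               q_start=0, q_end=0)
    i, j, state = bi, bj, "H"
    matches = columns = 0
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            if H[i][j] == H[i - 1][j - 1] + sub(q[i - 1], t[j - 1]):
                columns += 1
                if q[i - 1] == t[j - 1] and q[i - 1] in "ACGT":
                    matches += 1
                i -= 1
                j -= 1
            elif H[i][j] == F[i][j]:
                state = "F"
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                raise AssertionError("inconsistent oracle traceback")
        elif state == "F":
            columns += 1
            if F[i][j] == H[i - 1][j] + gap_open:
                state = "H"
            i -= 1
        else:
            columns += 1
            if E[i][j] == H[i][j - 1] + gap_open:
                state = "H"
            j -= 1
    return OracleAlignment(score=best, identity=matches / columns,
                           coverage=(bi - i) / n, q_start=i, q_end=bi)


def best_over_strands(query: str, target: str) -> OracleAlignment:
    comp = str.maketrans("ACGTN", "TGCAN")
    fwd = smith_waterman(query, target)
    rev = smith_waterman(query.translate(comp)[::-1], target)
    return fwd if fwd.score >= rev.score else rev
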