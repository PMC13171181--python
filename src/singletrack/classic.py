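"""Classical dynamic-programming engine for (dual) gap-affine alignment.

The gap-affine recurrences over matrices M, I1, D1 (Gotoh):

    I1[i][j] = min(I1[i][j-1] + e1, M[i][j-1] + o1 + e1)
    D1[i][j] = min(D1[i-1][j] + e1, M[i-1][j] + o1 + e1)
    M[i][j]  = min(I1[i][j], D1[i][j], M[i-1][j-1] + S(i, j))

with a second pair of indel matrices (I2, D2 with penalties o2, e2) joining
the M-minimization in dual mode.  Insertions are horizontal moves (consume
target), deletions vertical (consume query).

Boundary conditions (standard Gotoh initialization):
M[0][0] = 0; for j >= 1, I1[0][j] = o1 + j*e1 (I2 analogous),
D*[0][j] = inf, M[0][j] = gap_cost(j); symmetric with I/D swapped for
column 0.

Two storage modes are provided.  ``fill_full`` keeps every matrix and
supports the classical backtrace.  ``fill_m_only`` keeps only M: under
column-wise iteration the horizontal recurrences need just the previous
column of I1 (and I2), while D1 (and D2) reduce to one carried scalar per
column, so the indel matrices never exist as whole matrices.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import List, Optional, TextIO

from .cigar import Cigar
from .penalties import PenaltySet, infinity_for, sat_add
from .result import AlignmentResult, TraceStats


@dataclass
class FullDPState:
    """All DP matrices, as nested lists indexed ``[i][j]`` (query, target)."""

    query: str
    target: str
    penalties: PenaltySet
    M: List[List[int]]
    I1: List[List[int]]
    D1: List[List[int]]
    I2: Optional[List[List[int]]] = None
    D2: Optional[List[List[int]]] = None
    inf: int = 0
    stats: TraceStats = field(default_factory=TraceStats)

    @property
    def n(self) -> int:
        return len(self.query)

    @property
    def m(self) -> int:
        return len(self.target)


@dataclass
class MOnlyDPState:
    """Only the M matrix is retained; indel matrices were never stored."""

    query: str
    target: str
    penalties: PenaltySet
    M: List[List[int]]
    inf: int = 0
    stats: TraceStats = field(default_factory=TraceStats)

    @property
    def n(self) -> int:
        return len(self.query)

    @property
    def m(self) -> int:
        return len(self.target)


def _sub_row(qc: str, target: str, a: int, x: int) -> List[int]:
    """Substitution costs of one query character against every target position."""
    qc = qc.upper()
    return [a if qc == tc.upper() else x for tc in target]


def fill_full(query: str, target: str, p: PenaltySet) -> FullDPState:
    """Column-wise fill retaining every matrix (3, or 5 in dual mode)."""
    n, m = len(query), len(target)
    inf = infinity_for(n, m, p)
    dual = p.dual
    o1, e1 = p.o1, p.e1

    M = [[0] * (m + 1) for _ in range(n + 1)]
    I1 = [[inf] * (m + 1) for _ in range(n + 1)]
    D1 = [[inf] * (m + 1) for _ in range(n + 1)]
    I2 = [[inf] * (m + 1) for _ in range(n + 1)] if dual else None
    D2 = [[inf] * (m + 1) for _ in range(n + 1)] if dual else None

    for i in range(1, n + 1):
        D1[i][0] = o1 + i * e1
        if dual:
            D2[i][0] = p.o2 + i * p.e2
        M[i][0] = p.gap_cost(i)
    for j in range(1, m + 1):
        I1[0][j] = o1 + j * e1
        if dual:
            I2[0][j] = p.o2 + j * p.e2
        M[0][j] = p.gap_cost(j)

    # Column-wise (j outer, i inner); any order would do with full storage.
    subs = [_sub_row(query[i - 1], target, p.a, p.x) for i in range(1, n + 1)]
    for j in range(1, m + 1):
        for i in range(1, n + 1):
            iv = min(I1[i][j - 1] + e1, M[i][j - 1] + o1 + e1)
            dv = min(D1[i - 1][j] + e1, M[i - 1][j] + o1 + e1)
            I1[i][j] = iv
            D1[i][j] = dv
            best = min(iv, dv, M[i - 1][j - 1] + subs[i - 1][j - 1])
            if dual:
                iv2 = min(I2[i][j - 1] + p.e2, M[i][j - 1] + p.o2 + p.e2)
                dv2 = min(D2[i - 1][j] + p.e2, M[i - 1][j] + p.o2 + p.e2)
                I2[i][j] = iv2
                D2[i][j] = dv2
                best = min(best, iv2, dv2)
            M[i][j] = best

    k = 5 if dual else 3
    stats = TraceStats(cells_stored_peak=k * (n + 1) * (m + 1))
    return FullDPState(query, target, p, M, I1, D1, I2, D2, inf, stats)


def fill_m_only(query: str, target: str, p: PenaltySet) -> MOnlyDPState:
    """Column-wise fill retaining only M.

    Per column, I1 (and I2) need the previous column only, and D1 (and D2)
    collapse to one carried scalar, so storage is
    ``(n+1)(m+1) + (n+1) + 1`` cells (plus ``(n+1) + 1`` more in dual mode).
    """
    n, m = len(query), len(target)
    inf = infinity_for(n, m, p)
    dual = p.dual
    o1, e1 = p.o1, p.e1

    M = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        M[i][0] = p.gap_cost(i)
    icol1 = [inf] * (n + 1)  # I1 previous column
    icol2 = [inf] * (n + 1) if dual else None

    subs = [_sub_row(query[i - 1], target, p.a, p.x) for i in range(1, n + 1)]
    for j in range(1, m + 1):
        M[0][j] = p.gap_cost(j)
        new1 = [o1 + j * e1] + [0] * n
        new2 = [p.o2 + j * p.e2] + [0] * n if dual else None
        dcar1 = inf  # D1[i-1][j], carried down the column
        dcar2 = inf
        for i in range(1, n + 1):
            iv = min(icol1[i] + e1, M[i][j - 1] + o1 + e1)
            dv = min(dcar1 + e1, M[i - 1][j] + o1 + e1) if dcar1 < inf else M[i - 1][j] + o1 + e1
            new1[i] = iv
            dcar1 = dv
            best = min(iv, dv, M[i - 1][j - 1] + subs[i - 1][j - 1])
            if dual:
                iv2 = min(icol2[i] + p.e2, M[i][j - 1] + p.o2 + p.e2)
                dv2 = min(dcar2 + p.e2, M[i - 1][j] + p.o2 + p.e2) if dcar2 < inf else M[i - 1][j] + p.o2 + p.e2
                new2[i] = iv2
                dcar2 = dv2
                best = min(best, iv2, dv2)
            M[i][j] = best
        icol1 = new1
        if dual:
            icol2 = new2

    stored = (n + 1) * (m + 1) + (n + 1) + 1
    if dual:
        stored += (n + 1) + 1
    return MOnlyDPState(query, target, p, M, inf, TraceStats(cells_stored_peak=stored))


def classical_backtrace(state: FullDPState) -> AlignmentResult:
    """Backtrace reading all matrices; requires a full-storage fill.

    Predecessors at an M cell are examined in fixed order: diagonal
    (match/mismatch), then I1, D1, I2, D2; the first consistent transition
    wins.  ``cells_explored`` counts one per backtrace step (per landing
    cell on the chosen path, in whichever matrix), which equals the number
    of CIGAR unit operations.
    """
    if not isinstance(state, FullDPState):
        raise TypeError("classical backtrace needs the full-storage fill (indel matrices)")
    q, t, p = state.query, state.target, state.penalties
    n, m = state.n, state.m
    M, I1, D1 = state.M, state.I1, state.D1
    dual = p.dual
    explored = 0
    ops: List[str] = []

    from .penalties import substitution

    indel_classes = [("I", I1, p.o1, p.e1), ("D", D1, p.o1, p.e1)]
    if dual:
        indel_classes += [("I", state.I2, p.o2, p.e2), ("D", state.D2, p.o2, p.e2)]

    i, j = n, m
    matrix = "M"
    cls = None  # active indel class when matrix != "M"
    while i > 0 or j > 0:
        if matrix == "M":
            cur = M[i][j]
            if i > 0 and j > 0:
                s = substitution(q, t, i, j, p)
                if cur == M[i - 1][j - 1] + s:
                    ops.append("M" if s == p.a else "X")
                    i, j = i - 1, j - 1
                    explored += 1
                    continue
            for entry in indel_classes:
                kind, mat, _, _ = entry
                if kind == "I" and j > 0 and cur == mat[i][j]:
                    matrix, cls = "I", entry
                    break
                if kind == "D" and i > 0 and cur == mat[i][j]:
                    matrix, cls = "D", entry
                    break
            else:
                raise RuntimeError(
                    f"classical backtrace stuck at M[{i}][{j}]={cur}: no valid predecessor"
                )
            # switching matrices at the same cell is not a step
        elif matrix == "I":
            _, mat, o, e = cls
            cur = mat[i][j]
            ops.append("I")
            explored += 1
            if cur == M[i][j - 1] + o + e:
                i, j, matrix = i, j - 1, "M"
            elif j >= 2 and cur == mat[i][j - 1] + e:
                j -= 1
            else:
                raise RuntimeError(f"classical backtrace stuck in insertion at [{i}][{j}]")
        else:  # matrix == "D"
            _, mat, o, e = cls
            cur = mat[i][j]
            ops.append("D")
            explored += 1
            if cur == M[i - 1][j] + o + e:
                i, matrix = i - 1, "M"
            elif i >= 2 and cur == mat[i - 1][j] + e:
                i -= 1
            else:
                raise RuntimeError(f"classical backtrace stuck in deletion at [{i}][{j}]")

    cigar = Cigar((op, 1) for op in reversed(ops))
    stats = TraceStats(
        cells_stored_peak=state.stats.cells_stored_peak,
        cells_explored=explored,
    )
    return AlignmentResult(M[n][m], cigar, stats, engine="classic", backtrace="classical")


def dump_matrices(state: FullDPState, out: TextIO = sys.stdout) -> None:
    """Tab-separated debug dump (rows = query, cols = target), 'inf' sentinel."""
    names = [("M", state.M), ("I1", state.I1), ("D1", state.D1)]
    if state.penalties.dual:
        names += [("I2", state.I2), ("D2", state.D2)]
    for name, mat in names:
        print(f"# {name}", file=out)
        for row in mat:
            print("\t".join("inf" if v >= state.inf else str(v) for v in row), file=out)
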