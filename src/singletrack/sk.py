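"""Difference-encoded (Suzuki-Kasahara) engine.

Instead of absolute scores, the fill stores adjacent-cell differences of M:

    dH[i][j] = M[i][j] - M[i][j-1]        (horizontal)
    dV[i][j] = M[i][j] - M[i-1][j]        (vertical)

together with transient per-column differences of the indel matrices
relative to M, dE1[i][j] = I1[i][j] - M[i][j] and
dF1[i][j] = D1[i][j] - M[i][j] (dE2/dF2 in dual mode), and the temporary
diagonal difference A[i][j] = M[i][j] - M[i-1][j-1].  Substituting the
definitions into the gap-affine recurrences gives

    A[i][j]  = min( S(i, j),
                    min(dE1[i][j-1] + e1, o1 + e1) + dV[i][j-1],
                    min(dF1[i-1][j] + e1, o1 + e1) + dH[i-1][j] )
    dH[i][j] = A[i][j] - dV[i][j-1]
    dV[i][j] = A[i][j] - dH[i-1][j]
    dE1[i][j] = min(dE1[i][j-1] + e1, o1 + e1) - dH[i][j]
    dF1[i][j] = min(dF1[i-1][j] + e1, o1 + e1) - dV[i][j]

(dual mode adds the analogous (o2, e2) terms to the A-minimization).  All
stored differences are small bounded integers, which is what enables the
narrow (e.g. 8-bit) encodings and SIMD kernels of production
implementations; this reference implementation keeps wide integers and
asserts the boundedness instead.

For the backtrace only dH and dV are needed.  Absolute M values are not
available, so the trace runs on the shifted matrix
M'[i][j] = M[i][j] - M[n][m], anchored at M'[n][m] = 0 and reconstructed
on the fly from the stored differences; the single-matrix backtrace is
shift-invariant, so nothing else changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .backtrace import BacktraceError, trace_m_only
from .cigar import Cigar
from .penalties import PenaltySet, infinity_for, substitution
from .result import AlignmentResult, TraceStats


@dataclass
class DiffState:
    """Stored difference matrices dH, dV (nested lists indexed [i][j]).

    ``dH[i][0]`` and ``dV[0][j]`` are undefined and hold an ``inf``
    sentinel that is never read.  ``dE1``/``dF1`` (and dual analogues) are
    only present when the fill was run with ``keep_ef=True``, emulating a
    full-retention difference fill for comparison purposes.
    """

    query: str
    target: str
    penalties: PenaltySet
    dH: List[List[int]]
    dV: List[List[int]]
    inf: int = 0
    dE1: Optional[List[List[int]]] = None
    dF1: Optional[List[List[int]]] = None
    dE2: Optional[List[List[int]]] = None
    dF2: Optional[List[List[int]]] = None
    stats: TraceStats = field(default_factory=TraceStats)

    @property
    def n(self) -> int:
        return len(self.query)

    @property
    def m(self) -> int:
        return len(self.target)


def fill_sk(query: str, target: str, p: PenaltySet, *, keep_ef: bool = False) -> DiffState:
    """Column-wise difference-encoded fill.

    Retains dH and dV for all cells (2 matrices, in both penalty modes);
    dE/dF live only as the current column plus a carried scalar.  With
    ``keep_ef=True`` the dE1/dF1 (and dual) matrices are additionally
    retained, modeling the full-retention variant.
    """
    n, m = len(query), len(target)
    inf = infinity_for(n, m, p)
    dual = p.dual
    o1, e1 = p.o1, p.e1

    def satmin_open(d: int, o: int, e: int) -> int:
        # min(dE + e, o + e) with dE possibly inf
        return o + e if d >= inf else min(d + e, o + e)

    dH = [[inf] * (m + 1) for _ in range(n + 1)]
    dV = [[inf] * (m + 1) for _ in range(n + 1)]
    kE1 = [[inf] * (m + 1) for _ in range(n + 1)] if keep_ef else None
    kF1 = [[inf] * (m + 1) for _ in range(n + 1)] if keep_ef else None
    kE2 = [[inf] * (m + 1) for _ in range(n + 1)] if keep_ef and dual else None
    kF2 = [[inf] * (m + 1) for _ in range(n + 1)] if keep_ef and dual else None

    # Border differences: column 0 vertical; dF relative to M on column 0.
    for i in range(1, n + 1):
        dV[i][0] = p.gap_cost(i) - (p.gap_cost(i - 1) if i > 1 else 0)
    if keep_ef:
        for i in range(1, n + 1):
            kF1[i][0] = (o1 + i * e1) - p.gap_cost(i)
            if dual:
                kF2[i][0] = (p.o2 + i * p.e2) - p.gap_cost(i)

    dE_prev = [inf] * (n + 1)  # dE1 of the previous column (col 0: I1 unreachable)
    dE2_prev = [inf] * (n + 1)

    subs = [
        [p.a if query[i - 1].upper() == tc.upper() else p.x for tc in target]
        for i in range(1, n + 1)
    ]

    for j in range(1, m + 1):
        dH[0][j] = p.gap_cost(j) - (p.gap_cost(j - 1) if j > 1 else 0)
        dE_new = [inf] * (n + 1)
        dE2_new = [inf] * (n + 1)
        dE_new[0] = (o1 + j * e1) - p.gap_cost(j)
        if dual:
            dE2_new[0] = (p.o2 + j * p.e2) - p.gap_cost(j)
        # dF1[0][j] = inf for j >= 1 (D matrices unreachable on the top row)
        dF_cur = inf
        dF2_cur = inf
        for i in range(1, n + 1):
            iterm = satmin_open(dE_prev[i], o1, e1)
            dterm = satmin_open(dF_cur, o1, e1)
            a_val = min(
                subs[i - 1][j - 1],
                iterm + dV[i][j - 1],
                dterm + dH[i - 1][j],
            )
            if dual:
                iterm2 = satmin_open(dE2_prev[i], p.o2, p.e2)
                dterm2 = satmin_open(dF2_cur, p.o2, p.e2)
                a_val = min(a_val, iterm2 + dV[i][j - 1], dterm2 + dH[i - 1][j])
            dH[i][j] = a_val - dV[i][j - 1]
            dV[i][j] = a_val - dH[i - 1][j]
            dE_new[i] = iterm - dH[i][j]
            dF_cur = dterm - dV[i][j]
            if dual:
                dE2_new[i] = iterm2 - dH[i][j]
                dF2_cur = dterm2 - dV[i][j]
            if keep_ef:
                kE1[i][j] = dE_new[i]
                kF1[i][j] = dF_cur
                if dual:
                    kE2[i][j] = dE2_new[i]
                    kF2[i][j] = dF2_cur
        if keep_ef:
            kE1[0][j] = dE_new[0]
            if dual:
                kE2[0][j] = dE2_new[0]
        dE_prev = dE_new
        dE2_prev = dE2_new

    k = 4 if keep_ef and not dual else (6 if keep_ef else 2)
    stats = TraceStats(cells_stored_peak=k * (n + 1) * (m + 1))
    return DiffState(query, target, p, dH, dV, inf, kE1, kF1, kE2, kF2, stats)


def reconstruct_m(diff: DiffState) -> List[List[int]]:
    """Rebuild absolute M by cumulative sums of the stored differences.

    Test/debug helper: reads only dH/dV.  Row 0 accumulates dH; each later
    row accumulates dV down column 0 then dH across.
    """
    n, m = diff.n, diff.m
    M = [[0] * (m + 1) for _ in range(n + 1)]
    for j in range(1, m + 1):
        M[0][j] = M[0][j - 1] + diff.dH[0][j]
    for i in range(1, n + 1):
        M[i][0] = M[i - 1][0] + diff.dV[i][0]
        for j in range(1, m + 1):
            M[i][j] = M[i][j - 1] + diff.dH[i][j]
    return M


class _ShiftedM:
    """Lazy reconstruction of M'[i][j] = M[i][j] - M[n][m] from dH/dV.

    Anchored at M'[n][m] = 0.  A value is computed by walking right along
    its row to the nearest memoized cell (falling back to the anchor
    column, itself filled downward with dV), accumulating dH; memoized
    values cover only the cells the backtrace actually touches.
    """

    def __init__(self, diff: DiffState):
        self._dH = diff.dH
        self._dV = diff.dV
        self._n = diff.n
        self._m = diff.m
        self._memo: Dict[Tuple[int, int], int] = {(diff.n, diff.m): 0}
        self._rowbase: Dict[int, int] = {diff.n: 0}  # M'[i][m]

    def _row_anchor(self, i: int) -> int:
        base = self._rowbase.get(i)
        if base is None:
            # climb from the nearest known row anchor below
            k = i
            known = [r for r in self._rowbase if r >= i]
            src = min(known)
            val = self._rowbase[src]
            for r in range(src, i, -1):
                val -= self._dV[r][self._m]
                self._rowbase[r - 1] = val
            base = self._rowbase[i]
        return base

    def get(self, i: int, j: int) -> int:
        memo = self._memo
        v = memo.get((i, j))
        if v is not None:
            return v
        # walk right to the nearest memoized cell, else the anchor column
        jj = j
        while jj < self._m and (i, jj) not in memo:
            jj += 1
        val = memo.get((i, jj))
        if val is None:
            val = self._row_anchor(i)
            memo[(i, self._m)] = val
        for c in range(jj, j, -1):
            val -= self._dH[i][c]
            memo[(i, c - 1)] = val
        return val


def sk_singletrack_backtrace(diff: DiffState) -> AlignmentResult:
    """Single-matrix backtrace over the shifted matrix M'.

    Reads only dH/dV; the score is recovered as -M'[0][0] at the end of
    the trace (M'[0][0] = -M[n][m]).
    """
    q, t, p = diff.query, diff.target, diff.penalties
    n, m = diff.n, diff.m
    shifted = _ShiftedM(diff)
    floor = shifted.get(0, 0)  # = -score, the least value in M'
    cigar, cost, explored = trace_m_only(
        n, m, shifted.get, lambda i, j: substitution(q, t, i, j, p), p, floor=floor
    )
    score = -floor
    if cost != score:
        raise BacktraceError(f"reconstructed trace cost {cost} != score {score}")
    stats = TraceStats(
        cells_stored_peak=diff.stats.cells_stored_peak,
        cells_explored=explored,
    )
    return AlignmentResult(score, cigar, stats, engine="sk", backtrace="singletrack")


def sk_classical_backtrace(diff: DiffState) -> AlignmentResult:
    """Classical-style backtrace over the difference encoding.

    Requires the full-retention fill (``keep_ef=True``) because the
    classical procedure consults the indel matrices; transitions are
    evaluated purely on differences:

    - diagonal:       dH[i][j] + dV[i][j-1] == S(i, j)
    - enter I-class:  dE[i][j] == 0 (M[i][j] == I[i][j])
    - I gap open:     dE[i][j] + dH[i][j] == o + e
    - I gap extend:   otherwise (predecessor I[i][j-1])

    and symmetrically for D-classes with dV.
    """
    if diff.dE1 is None:
        raise TypeError("classical backtrace over differences needs fill_sk(keep_ef=True)")
    q, t, p = diff.query, diff.target, diff.penalties
    n, m = diff.n, diff.m
    dH, dV = diff.dH, diff.dV
    inf = diff.inf
    dual = p.dual

    # absolute score, reconstructed from differences only
    score = 0
    for i in range(1, n + 1):
        score += dV[i][0]
    for j in range(1, m + 1):
        score += dH[n][j]

    classes = [("I", diff.dE1, dH, p.o1, p.e1), ("D", diff.dF1, dV, p.o1, p.e1)]
    if dual:
        classes += [("I", diff.dE2, dH, p.o2, p.e2), ("D", diff.dF2, dV, p.o2, p.e2)]

    ops: List[str] = []
    explored = 0
    i, j = n, m
    matrix = "M"
    active = None
    while i > 0 or j > 0:
        if matrix == "M":
            if i > 0 and j > 0:
                s = substitution(q, t, i, j, p)
                if dH[i][j] + dV[i][j - 1] == s:
                    ops.append("M" if s == p.a else "X")
                    explored += 1
                    i, j = i - 1, j - 1
                    continue
            for entry in classes:
                kind, dEF, _, _, _ = entry
                if kind == "I" and j > 0 and dEF[i][j] == 0:
                    matrix, active = "I", entry
                    break
                if kind == "D" and i > 0 and dEF[i][j] == 0:
                    matrix, active = "D", entry
                    break
            else:
                raise BacktraceError(f"difference backtrace stuck at ({i},{j})")
        elif matrix == "I":
            _, dEF, _, o, e = active
            ops.append("I")
            explored += 1
            if dEF[i][j] + dH[i][j] == o + e:
                j, matrix = j - 1, "M"
            else:
                j -= 1
        else:
            _, dEF, _, o, e = active
            ops.append("D")
            explored += 1
            if dEF[i][j] + dV[i][j] == o + e:
                i, matrix = i - 1, "M"
            else:
                i -= 1

    cigar = Cigar((op, 1) for op in reversed(ops))
    stats = TraceStats(
        cells_stored_peak=diff.stats.cells_stored_peak, cells_explored=explored
    )
    return AlignmentResult(score, cigar, stats, engine="sk", backtrace="classical")
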