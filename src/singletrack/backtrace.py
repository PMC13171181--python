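"""Single-matrix ("singletrack") backtrace for (dual) gap-affine alignments.

The indel recurrences depend only on M and on themselves, so a backtrace
never has to read a stored indel score: when the predecessor of an M cell
is not the diagonal, the gap that ends there can be resolved by advancing
tentative insertion and deletion paths in lock-step over the gap length
``l`` and testing the closed-form return score

    s(l) = M[i][j] - o_k - l * e_k

against stored M cells: the gap is an insertion of length ``l`` when
``M[i][j-l] == s(l)`` and a deletion when ``M[i-l][j] == s(l)``.  Whenever
such an equality holds, appending the length-``l`` gap to an optimal
prefix at the return cell reproduces M[i][j] exactly, so the resolved path
is optimal even if it differs from the one the classical backtrace picks.

In dual mode up to four tentative paths (I1, D1, I2, D2) advance together.
The core below is generic over an ``M`` accessor so the same code drives
both the classical engine (absolute scores) and the difference-encoded
engine (shifted scores M' = M - M[n,m]; every test above is invariant
under a constant shift).
"""

from __future__ import annotations

from typing import Callable, List, Tuple, Union

from .cigar import Cigar
from .penalties import PenaltySet
from .result import AlignmentResult, TraceStats
from .classic import FullDPState, MOnlyDPState


class BacktraceError(RuntimeError):
    """Internal-consistency failure: the stored M is not a valid fill."""


def _gap_classes(p: PenaltySet) -> List[Tuple[str, str, int, int]]:
    """Tentative path classes in fixed tie-break order I1, D1, I2, D2."""
    classes = [("I1", "I", p.o1, p.e1), ("D1", "D", p.o1, p.e1)]
    if p.dual:
        classes += [("I2", "I", p.o2, p.e2), ("D2", "D", p.o2, p.e2)]
    return classes


def _resolve(
    get: Callable[[int, int], int],
    i: int,
    j: int,
    cur: int,
    p: PenaltySet,
    floor: int = 0,
) -> Tuple[str, str, int, int]:
    """Resolve the gap ending at (i, j) with M-value ``cur``.

    Returns ``(kind, direction, l, probes)`` where kind is one of
    I1/D1/I2/D2, direction "I" or "D", ``l`` the gap length, and
    ``probes`` the number of M cells examined.  Tentative paths advance in
    lock-step over ``l`` so the first feasible length wins; among same-``l``
    hits the fixed class order applies.  At a border (i == 0 or j == 0)
    only the feasible direction is explored; return cells with negative
    index are skipped, not tested.
    """
    classes = _gap_classes(p)
    probes = 0
    for l in range(1, max(i, j) + 1):
        for kind, direction, o, e in classes:
            expected = cur - o - l * e
            if expected < floor:
                continue  # below the least stored value: this class can no longer return
            if direction == "I":
                if j - l < 0:
                    continue
                probes += 1
                if get(i, j - l) == expected:
                    return kind, direction, l, probes
            else:
                if i - l < 0:
                    continue
                probes += 1
                if get(i - l, j) == expected:
                    return kind, direction, l, probes
    raise BacktraceError(
        f"no gap return found from ({i},{j}) with value {cur}: "
        "inconsistent fill or penalty/state mismatch"
    )


def trace_m_only(
    n: int,
    m: int,
    get: Callable[[int, int], int],
    sub: Callable[[int, int], int],
    p: PenaltySet,
    floor: int = 0,
) -> Tuple[Cigar, int, int]:
    """Generic single-matrix backtrace.

    ``get(i, j)`` returns the (possibly shifted) M value; ``sub(i, j)`` the
    1-based substitution cost.  Returns ``(cigar, cost_drop, explored)``
    where ``cost_drop = get(n, m) - get(0, 0)`` equals the alignment cost.
    ``explored`` counts one per M cell probed on any tentative path plus
    one per committed match/mismatch step.  ``floor`` is a lower bound on
    stored values (0 for absolute scores, ``-score`` in shifted space)
    used to abandon tentative paths whose return score falls below it.
    """
    ops: List[str] = []
    explored = 0
    i, j = n, m
    cur = get(n, m)
    start = cur
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = sub(i, j)
            prev = get(i - 1, j - 1)
            if cur == prev + s:
                ops.append("M" if s == p.a else "X")
                explored += 1
                i, j, cur = i - 1, j - 1, prev
                continue
        kind, direction, l, probes = _resolve(get, i, j, cur, p, floor)
        explored += probes
        o, e = dict(I1=(p.o1, p.e1), D1=(p.o1, p.e1),
                    I2=(p.o2, p.e2), D2=(p.o2, p.e2))[kind]
        cur = cur - o - l * e
        if direction == "I":
            ops.extend("I" * l)
            j -= l
        else:
            ops.extend("D" * l)
            i -= l
    cigar = Cigar((op, 1) for op in reversed(ops))
    return cigar, start - cur, explored


def singletrack_backtrace(
    state: Union[FullDPState, MOnlyDPState]
) -> AlignmentResult:
    """Single-matrix backtrace over a classical fill.

    Accepts either storage mode but reads only ``state.M``; running it
    against :class:`MOnlyDPState`, where the indel matrices do not exist,
    enforces that property structurally.
    """
    q, t, p = state.query, state.target, state.penalties
    n, m = state.n, state.m
    M = state.M

    from .penalties import substitution

    cigar, cost, explored = trace_m_only(
        n, m, lambda i, j: M[i][j], lambda i, j: substitution(q, t, i, j, p), p
    )
    if cost != M[n][m]:
        raise BacktraceError(f"trace cost {cost} != M[n][m] = {M[n][m]}")
    stats = TraceStats(
        cells_stored_peak=state.stats.cells_stored_peak,
        cells_explored=explored,
    )
    return AlignmentResult(M[n][m], cigar, stats, engine="classic", backtrace="singletrack")


def resolve_gap(
    state: Union[FullDPState, MOnlyDPState], i: int, j: int, p: PenaltySet
) -> Tuple[str, int]:
    """Resolve the maximal gap run ending at M[i][j]; returns (kind, length).

    Precondition: the predecessor of (i, j) is in an indel matrix, i.e.
    the diagonal transition does not explain M[i][j].
    """
    M = state.M
    kind, _, l, _ = _resolve(lambda a, b: M[a][b], i, j, M[i][j], p)
    return kind, l
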