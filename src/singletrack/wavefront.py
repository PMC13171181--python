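"""Wavefront alignment engine (WFA) for (dual) gap-affine penalties.

For each score ``z`` and diagonal ``k = j - i`` (target column minus query
row), the wavefront stores the furthest-reaching target column ``j``
attainable at cost ``z``, per component (M, I1, D1 and, in dual mode, I2,
D2).  Cost-minimizing recurrences (offsets maximize):

    I1[z][k] = max(M[z-o1-e1][k-1], I1[z-e1][k-1]) + 1
    D1[z][k] = max(M[z-o1-e1][k+1], D1[z-e1][k+1])
    M[z][k]  = max(M[z-x][k] + 1, I1[z][k], D1[z][k])

followed by free diagonal extension of M offsets while characters match
(matches must cost 0, so the engine requires ``a == 0``).  Alignment
terminates at the first ``z`` whose M wavefront reaches ``(n, m)`` on
diagonal ``k = m - n``.

Two storage modes:

* ``baseline`` retains every component wavefront for every score (3
  vectors per score, 5 in dual mode) and supports the classical
  wavefront backtrace.
* ``singletrack`` retains only the M wavefronts (1 vector per score); the
  indel components live in a cyclic scope of
  ``N = max(x, o1 + e1[, o2 + e2]) + 1`` wavefronts whose slots are
  recycled as scores leave the dependency window.  Gaps are resolved at
  backtrace time by testing, for growing length ``l``, whether the gap's
  return point lies on the M wavefront of score ``z - o_k - l*e_k``
  (membership = the diagonal is in range and its furthest-reaching offset
  covers the point).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .cigar import Cigar
from .penalties import PenaltySet
from .result import AlignmentResult, TraceStats


class WavefrontError(RuntimeError):
    """Internal-consistency failure during wavefront backtrace."""


Wavefront = Dict[int, int]  # diagonal k -> furthest-reaching target column j


@dataclass
class WavefrontStack:
    """Wavefronts retained after a forward pass, plus bookkeeping."""

    query: str
    target: str
    penalties: PenaltySet
    mode: str  # "baseline" | "singletrack"
    score: int
    M: List[Optional[Wavefront]]
    I1: Optional[List[Optional[Wavefront]]] = None
    D1: Optional[List[Optional[Wavefront]]] = None
    I2: Optional[List[Optional[Wavefront]]] = None
    D2: Optional[List[Optional[Wavefront]]] = None
    indel_scope: int = 0
    stats: TraceStats = field(default_factory=TraceStats)

    @property
    def n(self) -> int:
        return len(self.query)

    @property
    def m(self) -> int:
        return len(self.target)


class _CyclicScope:
    """Fixed window of indel wavefronts, recycled as scores advance.

    Slot ``z % N`` holds the wavefront for score ``z``; writing score
    ``z`` evicts score ``z - N``.  Reads outside the live window return
    None, mirroring a dropped wavefront.
    """

    def __init__(self, depth: int):
        self.depth = depth
        self._slots: List[Optional[tuple]] = [None] * depth

    def put(self, z: int, wf: Optional[Wavefront]) -> None:
        self._slots[z % self.depth] = (z, wf)

    def get(self, z: int) -> Optional[Wavefront]:
        if z < 0:
            return None
        slot = self._slots[z % self.depth]
        if slot is None or slot[0] != z:
            return None
        return slot[1]

    def live_cells(self) -> int:
        return sum(len(s[1]) for s in self._slots if s is not None and s[1])


def _extend(offset: int, k: int, q: str, t: str, n: int, m: int) -> int:
    """Advance an M offset along diagonal k while characters match."""
    j = offset
    i = j - k
    while j < m and i < n and q[i] == t[j]:
        j += 1
        i += 1
    return j


def wfa_align(query: str, target: str, p: PenaltySet, *, mode: str = "singletrack") -> WavefrontStack:
    """Forward wavefront pass; returns the retained wavefronts and score.

    ``mode="baseline"`` keeps all components; ``mode="singletrack"`` keeps
    only the M wavefronts and cycles the indel components through a
    minimal dependency window.
    """
    if p.a != 0:
        raise ValueError(
            "the wavefront engine requires a == 0 (free matches); "
            f"got a={p.a}: renormalize the penalties or use another engine"
        )
    if mode not in ("baseline", "singletrack"):
        raise ValueError(f"unknown wavefront mode {mode!r}")
    q = query.upper()
    t = target.upper()
    n, m = len(q), len(t)
    x, o1, e1 = p.x, p.o1, p.e1
    dual = p.dual
    k_final = m - n

    classes = [(o1, e1)]
    if dual:
        classes.append((p.o2, p.e2))
    scope_n = max([x] + [o + e for o, e in classes]) + 1

    M: List[Optional[Wavefront]] = []
    if mode == "baseline":
        I1s: List[Optional[Wavefront]] = []
        D1s: List[Optional[Wavefront]] = []
        I2s: List[Optional[Wavefront]] = [] if dual else None
        D2s: List[Optional[Wavefront]] = [] if dual else None

        def put_indel(z, i1, d1, i2, d2):
            I1s.append(i1)
            D1s.append(d1)
            if dual:
                I2s.append(i2)
                D2s.append(d2)

        def get_I(cls_idx, z):
            src = I1s if cls_idx == 0 else I2s
            return src[z] if 0 <= z < len(src) else None

        def get_D(cls_idx, z):
            src = D1s if cls_idx == 0 else D2s
            return src[z] if 0 <= z < len(src) else None
    else:
        scopes = [( _CyclicScope(scope_n), _CyclicScope(scope_n)) for _ in classes]

        def put_indel(z, i1, d1, i2, d2):
            scopes[0][0].put(z, i1)
            scopes[0][1].put(z, d1)
            if dual:
                scopes[1][0].put(z, i2)
                scopes[1][1].put(z, d2)

        def get_I(cls_idx, z):
            return scopes[cls_idx][0].get(z)

        def get_D(cls_idx, z):
            return scopes[cls_idx][1].get(z)

    def get_M(z: int) -> Optional[Wavefront]:
        return M[z] if 0 <= z < len(M) else None

    peak_indel = 0

    # score 0: pure extension from the origin
    wf0: Wavefront = {0: _extend(0, 0, q, t, n, m)}
    M.append(wf0)
    put_indel(0, None, None, None, None)

    def done(z: int) -> bool:
        wf = M[z]
        return wf is not None and wf.get(k_final, -1) >= m

    if done(0):
        s = 0
    else:
        # hard upper bound on the optimal score: full-gap alignment
        z_bound = (p.gap_cost(n) if n else 0) + (p.gap_cost(m) if m else 0) + 1
        s = -1
        z = 0
        while s < 0:
            z += 1
            if z > z_bound:
                raise WavefrontError("wavefront pass exceeded the score bound")
            new_I: List[Optional[Wavefront]] = []
            new_D: List[Optional[Wavefront]] = []
            for ci, (o, e) in enumerate(classes):
                m_open = get_M(z - o - e)
                i_ext = get_I(ci, z - e)
                d_ext = get_D(ci, z - e)
                iwf: Wavefront = {}
                ks = set()
                if m_open:
                    ks |= {k + 1 for k in m_open}
                if i_ext:
                    ks |= {k + 1 for k in i_ext}
                for k in ks:
                    best = -1
                    if m_open is not None and k - 1 in m_open:
                        best = m_open[k - 1]
                    if i_ext is not None and k - 1 in i_ext:
                        best = max(best, i_ext[k - 1])
                    j = best + 1
                    if best >= 0 and j <= m and 0 <= j - k <= n:
                        iwf[k] = j
                dwf: Wavefront = {}
                ks = set()
                if m_open:
                    ks |= {k - 1 for k in m_open}
                if d_ext:
                    ks |= {k - 1 for k in d_ext}
                for k in ks:
                    best = -1
                    if m_open is not None and k + 1 in m_open:
                        best = m_open[k + 1]
                    if d_ext is not None and k + 1 in d_ext:
                        best = max(best, d_ext[k + 1])
                    if best >= 0 and 0 <= best - k <= n and best <= m:
                        dwf[k] = best
                new_I.append(iwf or None)
                new_D.append(dwf or None)

            m_mis = get_M(z - x)
            mwf: Wavefront = {}
            ks = set()
            if m_mis:
                ks |= set(m_mis)
            for comp in new_I + new_D:
                if comp:
                    ks |= set(comp)
            for k in ks:
                best = -1
                if m_mis is not None and k in m_mis:
                    j = m_mis[k] + 1
                    if j <= m and 0 <= j - k <= n:
                        best = j
                for comp in new_I + new_D:
                    if comp and k in comp:
                        best = max(best, comp[k])
                if best >= 0:
                    mwf[k] = _extend(best, k, q, t, n, m)
            M.append(mwf or None)
            put_indel(
                z,
                new_I[0],
                new_D[0],
                new_I[1] if dual else None,
                new_D[1] if dual else None,
            )
            if mode == "singletrack":
                live = sum(sc[0].live_cells() + sc[1].live_cells() for sc in scopes)
                peak_indel = max(peak_indel, live)
            if done(z):
                s = z

    m_cells = sum(len(wf) for wf in M if wf)
    if mode == "baseline":
        indel_cells = sum(
            len(wf)
            for comp in (I1s, D1s, I2s or [], D2s or [])
            for wf in comp
            if wf
        )
        stats = TraceStats(
            cells_stored_peak=m_cells + indel_cells,
            wavefront_vectors_per_score=5 if dual else 3,
        )
        return WavefrontStack(
            query=q, target=t, penalties=p, mode=mode, score=s, M=M,
            I1=I1s, D1=D1s, I2=I2s, D2=D2s, indel_scope=scope_n, stats=stats,
        )
    stats = TraceStats(
        cells_stored_peak=m_cells + peak_indel,
        wavefront_vectors_per_score=1,
    )
    return WavefrontStack(
        query=q, target=t, penalties=p, mode=mode, score=s, M=M,
        indel_scope=scope_n, stats=stats,
    )


def wfa_classical_backtrace(stack: WavefrontStack) -> AlignmentResult:
    """Backtrace reading all component wavefronts (baseline mode only)."""
    if stack.mode != "baseline":
        raise TypeError("classical wavefront backtrace needs the baseline (all-component) fill")
    q, t, p = stack.query, stack.target, stack.penalties
    n, m = stack.n, stack.m
    x = p.x
    dual = p.dual

    def get(comp: Optional[List[Optional[Wavefront]]], z: int, k: int) -> Optional[int]:
        if comp is None or not (0 <= z < len(comp)):
            return None
        wf = comp[z]
        if wf is None:
            return None
        return wf.get(k)

    # (label, component-list, o, e, direction)
    gap_classes = [("I1", stack.I1, p.o1, p.e1, "I"), ("D1", stack.D1, p.o1, p.e1, "D")]
    if dual:
        gap_classes += [("I2", stack.I2, p.o2, p.e2, "I"), ("D2", stack.D2, p.o2, p.e2, "D")]

    ops: List[str] = []
    explored = 0
    state = "M"
    active = None
    z, k, j = stack.score, m - n, m
    while True:
        if state == "M":
            if z == 0:
                if k != 0:
                    raise WavefrontError("wavefront backtrace ended off the origin diagonal")
                ops.extend("M" * j)
                explored += j
                break
            cands = []
            mis = get(stack.M, z - x, k)
            if mis is not None and mis + 1 <= j:
                cands.append(("X", None, mis + 1))
            for label, comp, o, e, direction in gap_classes:
                v = get(comp, z, k)
                if v is not None and v <= j:
                    cands.append((direction, (label, comp, o, e, direction), v))
            if not cands:
                raise WavefrontError(f"no wavefront predecessor at z={z}, k={k}, j={j}")
            pre = max(c[2] for c in cands)
            ops.extend("M" * (j - pre))
            explored += j - pre
            j = pre
            chosen = next(c for c in cands if c[2] == pre)
            if chosen[0] == "X":
                ops.append("X")
                explored += 1
                z -= x
                j -= 1
            else:
                state = "G"
                active = chosen[1]
        else:  # inside a gap component
            label, comp, o, e, direction = active
            if direction == "I":
                opened = get(stack.M, z - o - e, k - 1)
                ops.append("I")
                explored += 1
                if opened is not None and opened == j - 1:
                    z, k, j, state = z - o - e, k - 1, j - 1, "M"
                else:
                    ext = get(comp, z - e, k - 1)
                    if ext is None or ext != j - 1:
                        raise WavefrontError(f"broken insertion chain at z={z}, k={k}")
                    z, k, j = z - e, k - 1, j - 1
            else:
                opened = get(stack.M, z - o - e, k + 1)
                ops.append("D")
                explored += 1
                if opened is not None and opened == j:
                    z, k, state = z - o - e, k + 1, "M"
                else:
                    ext = get(comp, z - e, k + 1)
                    if ext is None or ext != j:
                        raise WavefrontError(f"broken deletion chain at z={z}, k={k}")
                    z, k = z - e, k + 1

    cigar = Cigar((op, 1) for op in reversed(ops))
    stats = TraceStats(
        cells_stored_peak=stack.stats.cells_stored_peak,
        cells_explored=explored,
        wavefront_vectors_per_score=stack.stats.wavefront_vectors_per_score,
    )
    return AlignmentResult(stack.score, cigar, stats, engine="wfa", backtrace="classical")


def wfa_singletrack_backtrace(stack: WavefrontStack) -> AlignmentResult:
    """Backtrace reading only the M wavefronts.

    Works on either storage mode but never touches the indel components.
    A point (i, j) is a member of the M wavefront of score z iff its
    diagonal is in range and the stored furthest-reaching offset covers j
    (characters between j and the f.r.p. match by construction).
    """
    q, t, p = stack.query, stack.target, stack.penalties
    n, m = stack.n, stack.m
    x = p.x
    M = stack.M

    def member(z: int, i: int, j: int) -> bool:
        if z < 0 or z >= len(M) or M[z] is None:
            return False
        off = M[z].get(j - i)
        return off is not None and off >= j

    classes = [("I1", "I", p.o1, p.e1), ("D1", "D", p.o1, p.e1)]
    if p.dual:
        classes += [("I2", "I", p.o2, p.e2), ("D2", "D", p.o2, p.e2)]

    ops: List[str] = []
    explored = 0
    i, j, z = n, m, stack.score
    while i > 0 or j > 0:
        if i > 0 and j > 0 and q[i - 1] == t[j - 1]:
            # free match: always on an optimal path when a == 0
            ops.append("M")
            explored += 1
            i, j = i - 1, j - 1
            continue
        if i > 0 and j > 0 and z >= x:
            explored += 1
            if member(z - x, i - 1, j - 1):
                ops.append("X")
                i, j, z = i - 1, j - 1, z - x
                continue
        resolved = False
        for l in range(1, max(i, j) + 1):
            for label, direction, o, e in classes:
                z_ret = z - o - l * e
                if z_ret < 0:
                    continue
                if direction == "I":
                    if j - l < 0:
                        continue
                    explored += 1
                    if member(z_ret, i, j - l):
                        ops.extend("I" * l)
                        j, z = j - l, z_ret
                        resolved = True
                        break
                else:
                    if i - l < 0:
                        continue
                    explored += 1
                    if member(z_ret, i - l, j):
                        ops.extend("D" * l)
                        i, z = i - l, z_ret
                        resolved = True
                        break
            if resolved:
                break
        if not resolved:
            raise WavefrontError(f"no gap return from (i={i}, j={j}, z={z})")
    if z != 0:
        raise WavefrontError(f"backtrace reached the origin with residual score {z}")

    cigar = Cigar((op, 1) for op in reversed(ops))
    stats = TraceStats(
        cells_stored_peak=stack.stats.cells_stored_peak,
        cells_explored=explored,
        wavefront_vectors_per_score=1,
    )
    return AlignmentResult(stack.score, cigar, stats, engine="wfa", backtrace="singletrack")
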