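"""CIGAR representation and cost evaluation.

Operations: ``M`` (match), ``X`` (mismatch), ``I`` (insertion), ``D``
(deletion).  In this package's default orientation an insertion consumes a
*target* character (a horizontal move in the DP matrix) and a deletion
consumes a *query* character (a vertical move).  :meth:`Cigar.to_sam`
produces the SAM-convention string with I/D swapped.
"""

from __future__ import annotations

import re
from typing import Iterable, List, Tuple

from .penalties import PenaltySet, substitution

_VALID_OPS = frozenset("MXID")
_RUN_RE = re.compile(r"(\d+)([MXID])")


class CigarValidationError(ValueError):
    """Raised when a CIGAR is inconsistent with the sequences it claims to align."""


class Cigar:
    """Run-length encoded alignment operation sequence in canonical form.

    Adjacent runs always have distinct operations; run lengths are >= 1.
    """

    __slots__ = ("_ops",)

    def __init__(self, ops: Iterable[Tuple[str, int]] = ()):
        canonical: List[Tuple[str, int]] = []
        for op, length in ops:
            if op not in _VALID_OPS:
                raise ValueError(f"invalid CIGAR operation {op!r}")
            if not isinstance(length, int) or length < 1:
                raise ValueError(f"invalid run length {length!r} for op {op!r}")
            if canonical and canonical[-1][0] == op:
                canonical[-1] = (op, canonical[-1][1] + length)
            else:
                canonical.append((op, length))
        self._ops = tuple(canonical)

    @classmethod
    def from_expanded(cls, text: str) -> "Cigar":
        """Build from a per-operation string such as ``"MMIIM"``."""
        return cls((c, 1) for c in text)

    @classmethod
    def from_string(cls, text: str) -> "Cigar":
        """Parse a run-length string such as ``"2M2I1M"``."""
        if text == "":
            return cls()
        pos = 0
        ops = []
        for match in _RUN_RE.finditer(text):
            if match.start() != pos:
                raise ValueError(f"malformed CIGAR string {text!r}")
            ops.append((match.group(2), int(match.group(1))))
            pos = match.end()
        if pos != len(text):
            raise ValueError(f"malformed CIGAR string {text!r}")
        return cls(ops)

    @property
    def ops(self) -> Tuple[Tuple[str, int], ...]:
        return self._ops

    def expanded(self) -> str:
        """Per-operation string, e.g. ``"MMIIM"``."""
        return "".join(op * length for op, length in self._ops)

    def __str__(self) -> str:
        return "".join(f"{length}{op}" for op, length in self._ops)

    def __repr__(self) -> str:
        return f"Cigar({str(self)!r})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cigar):
            return NotImplemented
        return self._ops == other._ops

    def __hash__(self) -> int:
        return hash(self._ops)

    def __len__(self) -> int:
        """Total number of unit operations."""
        return sum(length for _, length in self._ops)

    def count(self, op: str) -> int:
        return sum(length for o, length in self._ops if o == op)

    @property
    def query_consumed(self) -> int:
        """Query characters consumed: M + X + D (deletions are vertical moves)."""
        return self.count("M") + self.count("X") + self.count("D")

    @property
    def target_consumed(self) -> int:
        """Target characters consumed: M + X + I (insertions are horizontal moves)."""
        return self.count("M") + self.count("X") + self.count("I")

    def to_sam(self) -> str:
        """Run-length string with I/D swapped to SAM semantics.

        SAM defines I as consuming the read (our query) and D the
        reference (our target), i.e. the opposite of this package's
        default orientation.
        """
        swap = {"I": "D", "D": "I", "M": "M", "X": "X"}
        return "".join(f"{length}{swap[op]}" for op, length in self._ops)


def cigar_cost(
    cigar: Cigar,
    query: str,
    target: str,
    p: PenaltySet,
    *,
    validate: bool = True,
) -> int:
    """Cost of an explicit alignment under a penalty set.

    Sums ``a`` per match, ``x`` per mismatch, and ``gap_cost(l)`` per
    *maximal* run of I (resp. D) of length ``l``.  Adjacent I and D runs
    are costed independently.  With ``validate=True`` (default) the CIGAR
    must consume exactly the two sequences, with M runs covering only
    equal characters and X runs only unequal ones.
    """
    if validate:
        if cigar.query_consumed != len(query) or cigar.target_consumed != len(target):
            raise CigarValidationError(
                f"CIGAR {cigar} consumes {cigar.query_consumed}/{cigar.target_consumed} "
                f"query/target characters but sequences have {len(query)}/{len(target)}"
            )
    total = 0
    i = j = 0  # 0-based consumed counts
    for run_idx, (op, length) in enumerate(cigar.ops):
        if op in ("M", "X"):
            for _ in range(length):
                s = substitution(query, target, i + 1, j + 1, p)
                if validate:
                    if op == "M" and s != p.a:
                        raise CigarValidationError(
                            f"run {run_idx} ({length}{op}): M over unequal characters "
                            f"q[{i}]={query[i]!r} vs t[{j}]={target[j]!r}"
                        )
                    if op == "X" and s != p.x:
                        raise CigarValidationError(
                            f"run {run_idx} ({length}{op}): X over equal characters "
                            f"q[{i}]={query[i]!r} vs t[{j}]={target[j]!r}"
                        )
                total += s
                i += 1
                j += 1
        elif op == "I":
            total += p.gap_cost(length)
            j += length
        else:  # D
            total += p.gap_cost(length)
            i += length
    return total
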