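"""Cost model for gap-affine and dual gap-affine pairwise alignment.

Alignment scores are *minimized integer costs*: a match costs ``a`` (usually
0), a mismatch ``x`` (with ``x > a``), and a gap of length ``l`` costs
``o1 + l*e1`` (gap-affine) or ``min(o1 + l*e1, o2 + l*e2)`` (dual
gap-affine, a.k.a. two-piece affine).  The dual model lets short gaps
(sequencing errors) and long gaps (single evolutionary events) be priced
with different slopes.

All arithmetic is exact integer arithmetic.  Unreachable dynamic-programming
states are represented by a large "infinity" sentinel with saturating
addition, so an overflowing border value can never masquerade as a real
score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Tuple


def infinity_for(n: int, m: int, p: "PenaltySet") -> int:
    """A per-alignment infinity sentinel.

    Strictly larger than any attainable alignment cost for sequences of
    lengths ``n`` and ``m``: every path has at most ``n + m`` unit
    operations, each costing at most ``max(x, o + e)``.
    """
    worst_unit = max(p.x, p.o1 + p.e1, (p.o2 + p.e2) if p.dual else 0)
    return (n + m + 2) * max(worst_unit, 1) + 1


def sat_add(a: int, b: int, inf: int) -> int:
    """Saturating addition: anything at or above ``inf`` stays ``inf``."""
    if a >= inf or b >= inf:
        return inf
    return a + b


@dataclass(frozen=True)
class PenaltySet:
    """Alignment penalties ``(a, x, o1, e1[, o2, e2])``.

    Parameters
    ----------
    a : int
        Match score, ``a >= 0``.
    x : int
        Mismatch penalty, ``x > a``.
    o1 : int
        Gap-open penalty of the first gap class, ``o1 >= 0``.
    e1 : int
        Gap-extend penalty of the first gap class, ``e1 >= 1``.
    o2, e2 : int, optional
        Second gap class; supplying both switches on dual gap-affine mode.
    """

    a: int
    x: int
    o1: int
    e1: int
    o2: Optional[int] = None
    e2: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("a", "x", "o1", "e1"):
            v = getattr(self, name)
            if not isinstance(v, int):
                raise TypeError(f"penalty {name!r} must be an integer, got {v!r}")
        if (self.o2 is None) != (self.e2 is None):
            raise ValueError("o2 and e2 must be given together")
        if self.a < 0:
            raise ValueError("match score a must be >= 0")
        if self.x <= self.a:
            raise ValueError("mismatch penalty x must exceed match score a")
        if self.o1 < 0:
            raise ValueError("gap-open o1 must be >= 0")
        if self.e1 < 1:
            raise ValueError("gap-extend e1 must be >= 1")
        if self.dual:
            if not isinstance(self.o2, int) or not isinstance(self.e2, int):
                raise TypeError("o2 and e2 must be integers")
            if self.o2 < 0:
                raise ValueError("gap-open o2 must be >= 0")
            if self.e2 < 1:
                raise ValueError("gap-extend e2 must be >= 1")

    @property
    def dual(self) -> bool:
        """True when a second gap class ``(o2, e2)`` is present."""
        return self.o2 is not None

    def gap_classes(self) -> Iterator[Tuple[int, int]]:
        """Yield each ``(open, extend)`` gap class in order."""
        yield (self.o1, self.e1)
        if self.dual:
            yield (self.o2, self.e2)  # type: ignore[misc]

    def gap_cost(self, l: int) -> int:
        """Cost of one maximal gap of length ``l >= 1``."""
        if l < 1:
            raise ValueError(f"gap length must be >= 1, got {l}")
        return min(o + l * e for o, e in self.gap_classes())

    # Common presets -------------------------------------------------------

    @classmethod
    def edit(cls) -> "PenaltySet":
        """Edit distance: a=0, x=1, unit gap extension, no opening cost."""
        return cls(0, 1, 0, 1)

    @classmethod
    def affine_default(cls) -> "PenaltySet":
        """Gap-affine defaults used by common read mappers: (0, 4, 6, 2)."""
        return cls(0, 4, 6, 2)

    @classmethod
    def dual_default(cls) -> "PenaltySet":
        """Dual gap-affine defaults: (0, 4, 6, 2) plus (o2=24, e2=1)."""
        return cls(0, 4, 6, 2, 24, 1)


def substitution(query: str, target: str, i: int, j: int, p: PenaltySet) -> int:
    """Cost of aligning query position ``i`` against target position ``j``.

    ``i`` and ``j`` are 1-based DP indices: the characters compared are
    ``query[i-1]`` and ``target[j-1]``.  Comparison is case-insensitive;
    any byte outside {A, C, G, T} is compared literally.
    """
    n, m = len(query), len(target)
    if not (1 <= i <= n):
        raise IndexError(f"query index {i} out of range 1..{n}")
    if not (1 <= j <= m):
        raise IndexError(f"target index {j} out of range 1..{m}")
    qc = query[i - 1]
    tc = target[j - 1]
    if qc == tc or qc.upper() == tc.upper():
        return p.a
    return p.x


def gap_cost(l: int, p: PenaltySet) -> int:
    """Module-level alias for :meth:`PenaltySet.gap_cost`."""
    return p.gap_cost(l)
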