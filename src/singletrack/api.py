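"""High-level alignment entry point dispatching over engines and backtraces."""

from __future__ import annotations

from typing import Optional

from .backtrace import singletrack_backtrace
from .classic import classical_backtrace, fill_full, fill_m_only
from .penalties import PenaltySet
from .result import AlignmentResult
from .sk import fill_sk, sk_classical_backtrace, sk_singletrack_backtrace
from .wavefront import wfa_align, wfa_classical_backtrace, wfa_singletrack_backtrace

ENGINES = ("classic", "sk", "wfa")
BACKTRACES = ("classical", "singletrack")


def align(
    query: str,
    target: str,
    penalties: Optional[PenaltySet] = None,
    *,
    engine: str = "classic",
    backtrace: str = "singletrack",
) -> AlignmentResult:
    """Globally align two sequences and return score, CIGAR, and stats.

    Parameters
    ----------
    query, target : str
        Sequences over a byte alphabet (case-insensitive comparison).
    penalties : PenaltySet, optional
        Defaults to the gap-affine preset (0, 4, 6, 2).
    engine : {"classic", "sk", "wfa"}
        Fill strategy: classical DP, difference-encoded DP, or wavefronts.
    backtrace : {"classical", "singletrack"}
        Classical backtraces read every stored structure and therefore use
        the full-storage fill; singletrack backtraces read only M (and use
        the reduced-storage fill).
    """
    p = penalties if penalties is not None else PenaltySet.affine_default()
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES}")
    if backtrace not in BACKTRACES:
        raise ValueError(f"unknown backtrace {backtrace!r}; choose from {BACKTRACES}")

    if engine == "classic":
        if backtrace == "classical":
            return classical_backtrace(fill_full(query, target, p))
        return singletrack_backtrace(fill_m_only(query, target, p))
    if engine == "sk":
        if backtrace == "classical":
            return sk_classical_backtrace(fill_sk(query, target, p, keep_ef=True))
        return sk_singletrack_backtrace(fill_sk(query, target, p))
    # wfa
    if backtrace == "classical":
        return wfa_classical_backtrace(wfa_align(query, target, p, mode="baseline"))
    return wfa_singletrack_backtrace(wfa_align(query, target, p, mode="singletrack"))
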