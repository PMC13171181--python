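"""Result and instrumentation containers shared by all engines."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .cigar import Cigar


@dataclass
class TraceStats:
    """Storage and backtrace-exploration counters.

    Attributes
    ----------
    cells_stored_peak : int
        Scalar score entries simultaneously retained at backtrace start
        (matrix cells for the DP engines, offsets for the wavefront engine).
    cells_explored : int
        Predecessor positions examined during backtrace.  Conventions:
        the classical backtrace counts one per landing cell on the chosen
        path (so it equals the number of CIGAR unit operations); the
        single-matrix backtrace counts one per M-cell probed on a
        tentative gap path plus one per committed match/mismatch step.
    wavefront_vectors_per_score : int or None
        Wavefront vectors retained per score value; only set by the
        wavefront engine (3 or 5 in baseline mode, 1 in single-matrix mode).
    """

    cells_stored_peak: int = 0
    cells_explored: int = 0
    wavefront_vectors_per_score: Optional[int] = None


@dataclass
class AlignmentResult:
    """Optimal score, alignment, and instrumentation for one pair."""

    score: int
    cigar: Cigar
    stats: TraceStats = field(default_factory=TraceStats)
    engine: str = ""
    backtrace: str = ""
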