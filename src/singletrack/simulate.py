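"""Synthetic pair generation, brute-force oracle, and dataset summaries.

The generator emulates the error profile used to characterize alignment
benchmarks: a random base sequence is copied with independent per-position
errors at a requested rate, split between mismatches and geometric-length
insertions/deletions.  The realized optimal error rate (edit operations
needed per base) can fall below the planted count because edits may cancel
or merge, so consumers should treat the planted count as an upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .cigar import Cigar, cigar_cost
from .penalties import PenaltySet

ALPHABET = "ACGT"


@dataclass(frozen=True)
class PairSpec:
    """Recipe for one synthetic query/target pair.

    Parameters
    ----------
    length : int
        Length of the base (query) sequence.
    error_rate : float
        Per-position probability of planting an edit, in [0, 1].
    mix : tuple of three floats
        Probabilities of (mismatch, insertion, deletion) given an edit;
        must sum to 1.  Default: equal thirds.
    geom_p : float
        Success probability of the geometric indel-length distribution
        (mean length 1/geom_p); default 0.5 (mean 2).
    seed : int
        Seed for the single pseudo-random source used throughout.
    """

    length: int
    error_rate: float
    mix: Tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    geom_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be >= 0")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if len(self.mix) != 3 or any(p < 0 for p in self.mix):
            raise ValueError("mix must be three non-negative probabilities")
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ValueError(f"mix probabilities must sum to 1, got {sum(self.mix)}")
        if not 0.0 < self.geom_p <= 1.0:
            raise ValueError("geom_p must lie in (0, 1]")


def generate_pair(spec: PairSpec) -> Tuple[str, str, int]:
    """Generate one (query, target, planted_edit_count) triple.

    The query is a uniform random sequence; the target is a mutated copy.
    Each query position independently receives an edit with probability
    ``error_rate``; the edit type follows ``mix`` and indel lengths are
    geometric.  The same spec (including seed) always yields the same
    pair.  The planted count is an upper bound on the optimal edit count.
    """
    rng = np.random.default_rng(spec.seed)
    query = "".join(rng.choice(list(ALPHABET), size=spec.length)) if spec.length else ""
    target_parts: List[str] = []
    planted = 0
    skip = 0
    for i, base in enumerate(query):
        if skip:
            skip -= 1
            continue
        if rng.random() >= spec.error_rate:
            target_parts.append(base)
            continue
        kind = rng.choice(3, p=list(spec.mix))
        if kind == 0:  # mismatch
            choices = [c for c in ALPHABET if c != base]
            target_parts.append(str(rng.choice(choices)))
            planted += 1
        elif kind == 1:  # insertion into the target
            l = int(rng.geometric(spec.geom_p))
            target_parts.append(base)
            target_parts.append("".join(rng.choice(list(ALPHABET), size=l)))
            planted += l
        else:  # deletion: drop this and the next l-1 query bases
            l = int(rng.geometric(spec.geom_p))
            skip = min(l, len(query) - i) - 1
            planted += skip + 1
    return query, "".join(target_parts), planted


def generate_dataset(
    length: int,
    error_rate: float,
    pairs: int,
    seed: int = 0,
    mix: Tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    geom_p: float = 0.5,
) -> List[Tuple[str, str, int]]:
    """Generate ``pairs`` independent pairs; pair ``i`` uses seed ``seed + i``."""
    return [
        generate_pair(PairSpec(length, error_rate, mix, geom_p, seed + i))
        for i in range(pairs)
    ]


def brute_force_score(query: str, target: str, p: PenaltySet, *, max_len: int = 8) -> int:
    """Minimum alignment cost by exhaustive path enumeration.

    Recursively enumerates every monotone alignment as a sequence of
    substitution steps and maximal gap runs (a run of one gap type is
    never followed immediately by another run of the same type, which
    makes runs maximal), costing each alignment with the same run-cost
    rule as :func:`singletrack.cigar.cigar_cost`.  No dynamic-programming
    tables are shared with the engines.  Exponential: refuses sequences
    longer than ``max_len``.
    """
    n, m = len(query), len(target)
    if n > max_len or m > max_len:
        raise ValueError(f"brute force capped at length {max_len}, got {n}x{m}")
    q = query.upper()
    t = target.upper()

    best = [None]

    def recurse(i: int, j: int, cost: int, prev_gap: str) -> None:
        if best[0] is not None and cost >= best[0]:
            return
        if i == n and j == m:
            best[0] = cost
            return
        if i < n and j < m:
            s = p.a if q[i] == t[j] else p.x
            recurse(i + 1, j + 1, cost + s, "")
        if prev_gap != "I":
            for l in range(1, m - j + 1):
                recurse(i, j + l, cost + p.gap_cost(l), "I")
        if prev_gap != "D":
            for l in range(1, n - i + 1):
                recurse(i + l, j, cost + p.gap_cost(l), "D")

    recurse(0, 0, 0, "")
    assert best[0] is not None
    return best[0]


def realized_error_rate(query: str, target: str) -> float:
    """Edit operations per base, via the edit-distance preset.

    Computed with the classical M-only fill under penalties
    (a=0, x=1, o=0, e=1), divided by max(len(query), len(target)).
    """
    from .classic import fill_m_only

    if not query and not target:
        return 0.0
    state = fill_m_only(query, target, PenaltySet.edit())
    return state.M[len(query)][len(target)] / max(len(query), len(target))


def summarize_dataset(pairs: Sequence[Tuple[str, str]] | Iterable) -> pd.DataFrame:
    """Per-dataset length and realized-error summary.

    ``pairs`` is a sequence of (query, target[, ...]) tuples.  Returns a
    one-row DataFrame with min/mean/max sequence lengths and the mean
    realized error rate under the edit-distance preset.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("summarize_dataset requires at least one pair")
    lengths: List[int] = []
    rates: List[float] = []
    for rec in pairs:
        q, t = rec[0], rec[1]
        lengths += [len(q), len(t)]
        rates.append(realized_error_rate(q, t))
    return pd.DataFrame(
        {
            "pairs": [len(pairs)],
            "min_length": [int(np.min(lengths))],
            "mean_length": [float(np.mean(lengths))],
            "max_length": [int(np.max(lengths))],
            "mean_error_rate": [float(np.mean(rates))],
        }
    )


def validate_result(query: str, target: str, p: PenaltySet, score: int, cigar: Cigar) -> None:
    """Assert that a CIGAR is a valid alignment whose cost equals ``score``."""
    cost = cigar_cost(cigar, query, target, p)
    if cost != score:
        raise AssertionError(f"CIGAR cost {cost} != reported score {score}")
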