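"""Tests of the single-matrix backtrace over the classical engine."""

import random

import pytest

from singletrack import (
    PenaltySet,
    cigar_cost,
    classical_backtrace,
    fill_full,
    fill_m_only,
    resolve_gap,
    singletrack_backtrace,
)
from conftest import random_pair


class TestWorkedExample:
    def test_cigar_matches_classical(self, worked):
        q, t, p = worked
        res = singletrack_backtrace(fill_m_only(q, t, p))
        assert res.score == 10
        assert res.cigar.expanded() == "MMIIM"

    def test_full_state_also_accepted(self, worked):
        q, t, p = worked
        res = singletrack_backtrace(fill_full(q, t, p))
        assert res.cigar.expanded() == "MMIIM"

    def test_gap_resolution_at_m_2_4(self, worked):
        # s(1) = 10-6-2 = 2 matches neither M[2][3] nor M[1][4];
        # s(2) = 10-6-4 = 0 = M[2][2]: insertion of length 2.
        q, t, p = worked
        state = fill_full(q, t, p)
        assert state.M[2][3] != 2 and state.M[1][4] != 2
        assert resolve_gap(state, 2, 4, p) == ("I1", 2)


class TestBoundariesAndDual:
    def test_boundary_insertion_run(self, affine):
        state = fill_m_only("", "AA", affine)
        res = singletrack_backtrace(state)
        assert res.cigar.expanded() == "II"
        assert resolve_gap(state, 0, 2, affine) == ("I1", 2)

    def test_identical_sequences_open_no_tentative_paths(self, affine):
        res = singletrack_backtrace(fill_m_only("ACGT", "ACGT", affine))
        assert res.cigar.expanded() == "MMMM"
        # every step is a committed diagonal, so explored == unit ops
        assert res.stats.cells_explored == 4

    def test_dual_long_deletion_resolved_as_second_class(self, dual):
        rng = random.Random(5)
        q = "".join(rng.choice("ACGT") for _ in range(80))
        t = q[:20] + q[50:]  # one 30-base deletion: o2 + 30*e2 < o1 + 30*e1
        full = fill_full(q, t, dual)
        classical = classical_backtrace(full)
        res = singletrack_backtrace(fill_m_only(q, t, dual))
        assert res.score == classical.score
        assert ("D", 30) in res.cigar.ops
        assert resolve_gap(full, 50, 20, dual) == ("D2", 30)


class TestAgainstClassical:
    @pytest.mark.parametrize("mode", ["affine", "dual"])
    def test_scores_and_validity_on_random_pairs(self, mode, affine, dual):
        p = affine if mode == "affine" else dual
        rng = random.Random(61)
        for _ in range(100):
            q, t = random_pair(rng, 60)
            classical = classical_backtrace(fill_full(q, t, p))
            res = singletrack_backtrace(fill_m_only(q, t, p))
            assert res.score == classical.score
            assert cigar_cost(res.cigar, q, t, p) == res.score

    @pytest.mark.parametrize("mode,factor", [("affine", 2), ("dual", 4)])
    def test_exploration_bound(self, mode, factor, affine, dual):
        p = affine if mode == "affine" else dual
        rng = random.Random(71)
        for _ in range(60):
            q, t = random_pair(rng, 60)
            if not q and not t:
                continue
            classical = classical_backtrace(fill_full(q, t, p))
            res = singletrack_backtrace(fill_m_only(q, t, p))
            assert res.stats.cells_explored <= factor * classical.stats.cells_explored

    def test_explored_at_least_unit_ops(self, affine):
        rng = random.Random(81)
        for _ in range(20):
            q, t = random_pair(rng, 40, min_len=1)
            res = singletrack_backtrace(fill_m_only(q, t, affine))
            assert res.stats.cells_explored >= len(res.cigar)


class TestStorageIsolation:
    def test_m_only_state_has_no_indel_matrices(self, worked):
        q, t, p = worked
        state = fill_m_only(q, t, p)
        assert not hasattr(state, "I1") and not hasattr(state, "D1")
        # the backtrace still succeeds reading M alone
        assert singletrack_backtrace(state).score == 10

    def test_mismatched_penalties_raise_consistency_error(self, worked):
        from singletrack import BacktraceError

        q, t, p = worked
        state = fill_m_only(q, t, p)
        state.penalties = PenaltySet(0, 7, 5, 3)  # not the fill's penalties
        with pytest.raises(BacktraceError):
            singletrack_backtrace(state)
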