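"""Tests of the wavefront engine and its two backtraces."""

import random

import pytest

from singletrack import (
    PenaltySet,
    cigar_cost,
    fill_full,
    wfa_align,
    wfa_classical_backtrace,
    wfa_singletrack_backtrace,
)
from conftest import random_pair


class TestForwardPass:
    def test_worked_example_score(self, worked):
        q, t, p = worked
        assert wfa_align(q, t, p).score == 10

    def test_identical_sequences_single_wavefront(self, affine):
        stack = wfa_align("ACGTACGT", "ACGTACGT", affine)
        assert stack.score == 0
        assert len(stack.M) == 1
        assert stack.M[0] == {0: 8}

    def test_refuses_nonzero_match_score(self):
        with pytest.raises(ValueError, match="a == 0"):
            wfa_align("A", "A", PenaltySet(1, 5, 3, 2))

    @pytest.mark.parametrize("mode", ["affine", "dual"])
    def test_scores_match_classic_engine(self, mode, affine, dual):
        p = affine if mode == "affine" else dual
        rng = random.Random(37)
        for _ in range(50):
            q, t = random_pair(rng, 60)
            expected = fill_full(q, t, p).M[len(q)][len(t)]
            assert wfa_align(q, t, p).score == expected

    def test_sparsity_on_similar_sequences(self, affine):
        rng = random.Random(47)
        q = "".join(rng.choice("ACGT") for _ in range(300))
        t = q[:100] + ("A" if q[100] != "A" else "C") + q[101:]
        stack = wfa_align(q, t, affine, mode="baseline")
        span = len(q) + len(t) + 1
        total = stack.stats.cells_stored_peak
        assert total <= (stack.score + 1) * span
        assert total < (len(q) + 1) * (len(t) + 1)

    def test_vectors_per_score(self, affine, dual):
        assert wfa_align("GCA", "GCCAA", affine, mode="baseline").stats.wavefront_vectors_per_score == 3
        assert wfa_align("GCA", "GCCAA", affine, mode="singletrack").stats.wavefront_vectors_per_score == 1
        assert wfa_align("GCA", "GCCAA", dual, mode="baseline").stats.wavefront_vectors_per_score == 5
        assert wfa_align("GCA", "GCCAA", dual, mode="singletrack").stats.wavefront_vectors_per_score == 1


class TestBacktraces:
    def test_worked_example_both_modes(self, worked):
        q, t, p = worked
        base = wfa_classical_backtrace(wfa_align(q, t, p, mode="baseline"))
        mini = wfa_singletrack_backtrace(wfa_align(q, t, p, mode="singletrack"))
        assert base.score == mini.score == 10
        assert cigar_cost(base.cigar, q, t, p) == 10
        assert cigar_cost(mini.cigar, q, t, p) == 10

    def test_forced_insertion_pair(self, affine):
        base = wfa_classical_backtrace(wfa_align("", "AA", affine, mode="baseline"))
        assert base.score == 10  # gap_cost(2)
        assert base.cigar.expanded() == "II"
        mini = wfa_singletrack_backtrace(wfa_align("", "AA", affine))
        assert mini.cigar.expanded() == "II"

    def test_identical_sequences_all_match(self, affine):
        res = wfa_singletrack_backtrace(wfa_align("ACGT", "ACGT", affine))
        assert res.cigar.expanded() == "MMMM"

    def test_classical_requires_baseline_storage(self, worked):
        q, t, p = worked
        with pytest.raises(TypeError):
            wfa_classical_backtrace(wfa_align(q, t, p, mode="singletrack"))

    @pytest.mark.parametrize("mode", ["affine", "dual"])
    def test_modes_agree_on_random_pairs(self, mode, affine, dual):
        p = affine if mode == "affine" else dual
        rng = random.Random(57)
        for _ in range(50):
            q, t = random_pair(rng, 60)
            base = wfa_classical_backtrace(wfa_align(q, t, p, mode="baseline"))
            mini = wfa_singletrack_backtrace(wfa_align(q, t, p, mode="singletrack"))
            assert base.score == mini.score
            assert cigar_cost(base.cigar, q, t, p) == base.score
            assert cigar_cost(mini.cigar, q, t, p) == mini.score
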