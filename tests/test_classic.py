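import random

import pytest

from singletrack import (
    PenaltySet,
    brute_force_score,
    cigar_cost,
    classical_backtrace,
    fill_full,
    fill_m_only,
)
from conftest import random_pair


class TestFillFull:
    def test_worked_example_cells(self, worked):
        q, t, p = worked
        state = fill_full(q, t, p)
        assert state.M[3][5] == 10
        assert state.I1[2][3] == 8
        assert state.M[2][2] == 0
        assert state.M[0][0] == 0

    def test_m_bounded_by_indel_matrices(self, worked):
        q, t, p = worked
        s = fill_full(q, t, p)
        for i in range(s.n + 1):
            for j in range(s.m + 1):
                if s.I1[i][j] < s.inf:
                    assert s.M[i][j] <= s.I1[i][j]
                if s.D1[i][j] < s.inf:
                    assert s.M[i][j] <= s.D1[i][j]

    def test_empty_sequences(self, affine):
        s = fill_full("", "", affine)
        assert s.M == [[0]]

    def test_stored_cell_count(self, affine, dual):
        s = fill_full("ACGT", "ACG", affine)
        assert s.stats.cells_stored_peak == 3 * 5 * 4
        s = fill_full("ACGT", "ACG", dual)
        assert s.stats.cells_stored_peak == 5 * 5 * 4


class TestFillMOnly:
    @pytest.mark.parametrize("mode", ["affine", "dual"])
    def test_m_identical_to_full_fill(self, mode, affine, dual):
        p = affine if mode == "affine" else dual
        rng = random.Random(11)
        for _ in range(15):
            q, t = random_pair(rng, 50)
            assert fill_m_only(q, t, p).M == fill_full(q, t, p).M

    def test_empty(self, affine):
        s = fill_m_only("", "", affine)
        assert s.M == [[0]]

    def test_stored_cell_count(self, affine, dual):
        n, m = 4, 3
        s = fill_m_only("ACGT", "ACG", affine)
        assert s.stats.cells_stored_peak == (n + 1) * (m + 1) + (n + 1) + 1
        s = fill_m_only("ACGT", "ACG", dual)
        assert s.stats.cells_stored_peak == (n + 1) * (m + 1) + 2 * ((n + 1) + 1)


class TestClassicalBacktrace:
    def test_worked_example(self, worked):
        q, t, p = worked
        res = classical_backtrace(fill_full(q, t, p))
        assert res.score == 10
        assert res.cigar.expanded() == "MMIIM"

    def test_identical_sequences(self, affine):
        res = classical_backtrace(fill_full("ACGTACGT", "ACGTACGT", affine))
        assert res.score == 0
        assert res.cigar.expanded() == "M" * 8

    def test_forced_insertion_run(self, affine):
        res = classical_backtrace(fill_full("", "AAA", affine))
        assert res.score == 12  # gap_cost(3) = 6 + 3*2
        assert res.cigar.expanded() == "III"

    def test_explored_equals_unit_ops(self, worked):
        q, t, p = worked
        res = classical_backtrace(fill_full(q, t, p))
        assert res.stats.cells_explored == len(res.cigar)

    def test_rejects_m_only_state(self, worked):
        q, t, p = worked
        with pytest.raises(TypeError):
            classical_backtrace(fill_m_only(q, t, p))


class TestScoreProperties:
    def test_oracle_equivalence_small(self, affine, dual):
        rng = random.Random(21)
        for trial in range(120):
            p = affine if trial % 2 else dual
            q, t = random_pair(rng, 6)
            assert fill_full(q, t, p).M[len(q)][len(t)] == brute_force_score(q, t, p)

    def test_symmetry_swaps_indel_roles(self, affine, dual):
        rng = random.Random(31)
        for trial in range(10):
            p = affine if trial % 2 else dual
            q, t = random_pair(rng, 40)
            from singletrack import Cigar

            fwd = classical_backtrace(fill_full(q, t, p))
            rev = classical_backtrace(fill_full(t, q, p))
            assert fwd.score == rev.score
            # swapping I/D roles turns the forward CIGAR into a valid,
            # equally costly alignment of the swapped pair
            swapped = Cigar.from_expanded(
                fwd.cigar.expanded().translate(str.maketrans("ID", "DI"))
            )
            assert cigar_cost(swapped, t, q, p) == rev.score

    def test_gap_linear_reduction(self):
        # with o1=0 the score equals the single-matrix gap-linear DP
        p = PenaltySet(0, 3, 0, 2)
        rng = random.Random(41)
        for _ in range(10):
            q, t = random_pair(rng, 30)
            n, m = len(q), len(t)
            M = [[0] * (m + 1) for _ in range(n + 1)]
            for i in range(1, n + 1):
                M[i][0] = i * p.e1
            for j in range(1, m + 1):
                M[0][j] = j * p.e1
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    s = p.a if q[i - 1] == t[j - 1] else p.x
                    M[i][j] = min(M[i][j - 1] + p.e1, M[i - 1][j] + p.e1,
                                  M[i - 1][j - 1] + s)
            assert fill_full(q, t, p).M[n][m] == M[n][m]

    def test_dual_degenerates_to_affine(self, affine):
        degenerate = PenaltySet(0, 4, 6, 2, 6, 2)
        rng = random.Random(51)
        for _ in range(10):
            q, t = random_pair(rng, 40)
            assert (
                fill_full(q, t, degenerate).M[len(q)][len(t)]
                == fill_full(q, t, affine).M[len(q)][len(t)]
            )
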