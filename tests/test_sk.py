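"""Tests of the difference-encoded (Suzuki-Kasahara) engine."""

import random

import pytest

from singletrack import (
    cigar_cost,
    fill_full,
    fill_sk,
    reconstruct_m,
    sk_classical_backtrace,
    sk_singletrack_backtrace,
)
from conftest import random_pair


class TestFillSK:
    @pytest.mark.parametrize("mode", ["affine", "dual"])
    def test_differences_match_classic_fill(self, mode, affine, dual):
        """dH/dV equal the finite differences of the classical M."""
        p = affine if mode == "affine" else dual
        rng = random.Random(7)
        for _ in range(8):
            q, t = random_pair(rng, 40)
            n, m = len(q), len(t)
            M = fill_full(q, t, p).M
            diff = fill_sk(q, t, p)
            for i in range(n + 1):
                for j in range(1, m + 1):
                    assert diff.dH[i][j] == M[i][j] - M[i][j - 1]
            for i in range(1, n + 1):
                for j in range(m + 1):
                    assert diff.dV[i][j] == M[i][j] - M[i - 1][j]

    def test_worked_example_reconstruction(self, worked):
        q, t, p = worked
        assert reconstruct_m(fill_sk(q, t, p))[3][5] == 10

    def test_single_character_chain(self, affine):
        diff = fill_sk("A", "A", affine)
        assert diff.dV[1][0] + diff.dH[1][1] == 0  # M[1][1] = a = 0

    def test_difference_boundedness(self, affine, dual):
        rng = random.Random(17)
        for p in (affine, dual):
            o_max = max(o for o, _ in p.gap_classes())
            e_max = max(e for _, e in p.gap_classes())
            bound = p.x + o_max + e_max
            q, t = random_pair(rng, 60)
            diff = fill_sk(q, t, p)
            for i in range(len(q) + 1):
                for j in range(1, len(t) + 1):
                    assert abs(diff.dH[i][j]) <= bound
            for i in range(1, len(q) + 1):
                for j in range(len(t) + 1):
                    assert abs(diff.dV[i][j]) <= bound

    def test_storage_counts_and_ratio(self, affine, dual):
        q, t = "ACGT", "ACG"
        cells = 5 * 4
        reduced = fill_sk(q, t, affine)
        full = fill_sk(q, t, affine, keep_ef=True)
        assert reduced.stats.cells_stored_peak == 2 * cells
        assert full.stats.cells_stored_peak == 4 * cells
        assert full.stats.cells_stored_peak / reduced.stats.cells_stored_peak == 2
        # dual mode never retains extra dE/dF in the reduced fill
        assert fill_sk(q, t, dual).stats.cells_stored_peak == 2 * cells


class TestSKBacktrace:
    def test_worked_example(self, worked):
        q, t, p = worked
        res = sk_singletrack_backtrace(fill_sk(q, t, p))
        assert res.score == 10
        assert cigar_cost(res.cigar, q, t, p) == 10

    def test_empty_query(self, affine):
        res = sk_singletrack_backtrace(fill_sk("", "AAA", affine))
        assert res.score == 12
        assert res.cigar.expanded() == "III"

    @pytest.mark.parametrize("mode", ["affine", "dual"])
    def test_scores_match_classic_engine(self, mode, affine, dual):
        p = affine if mode == "affine" else dual
        rng = random.Random(27)
        for _ in range(50):
            q, t = random_pair(rng, 60)
            expected = fill_full(q, t, p).M[len(q)][len(t)]
            res = sk_singletrack_backtrace(fill_sk(q, t, p))
            assert res.score == expected
            assert cigar_cost(res.cigar, q, t, p) == expected

    def test_classical_needs_full_retention(self, worked):
        q, t, p = worked
        with pytest.raises(TypeError):
            sk_classical_backtrace(fill_sk(q, t, p))
        res = sk_classical_backtrace(fill_sk(q, t, p, keep_ef=True))
        assert res.score == 10
        assert res.cigar.expanded() == "MMIIM"
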