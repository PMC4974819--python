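"""Sparse Four-Russians: signatures, G table, gating safety, dominance."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import assert_same_L
from rnassf import (
    GTable,
    OpCounters,
    SigIndex,
    complete,
    normalize_sequence,
    random_sequence,
    sig_dot,
    solve_fr,
    solve_naive,
    solve_sfr,
    solve_sparse,
)


class TestSigDot:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(0b01010, 0b01000, 1), (0b00010, 0b01000, 0), (0, 0b11111, 0), (0, 0, 0)],
    )
    def test_values(self, a, b, expected):
        assert sig_dot(a, b) == expected


class TestComplete:
    def _with_flags(self, seq):
        res = solve_naive(seq)
        dp = res.dp
        n = seq.n
        dp.oct = np.zeros((n + 1, n + 1), dtype=bool)
        dp.step = np.zeros((n + 1, n + 1), dtype=bool)
        return dp

    def test_forced_pair_sets_oct_bit(self):
        seq = normalize_sequence("GC")
        dp = self._with_flags(seq)
        sigs = SigIndex(q=1)
        m, step_rows = complete(dp, sigs, j=2, g=0)
        assert m == 1  # cell (0, 2) is OCT -> bit 0
        assert sigs.sig_oct[(0, 2)] == 1
        assert step_rows == [0]
        assert sigs.sig_step[(0, 2)] == 1  # STEP at (0,2): bit for column offset 0

    def test_pair_free_sequence_all_zero_signatures(self):
        seq = normalize_sequence("AAAAAA")
        dp = self._with_flags(seq)
        sigs = SigIndex(q=2)
        for j in range(2, 7):
            for g in range(j // 2 + 1):
                complete(dp, sigs, j=j, g=g)
        assert all(v == 0 for v in sigs.sig_oct.values())
        assert not sigs.sig_step

    def test_signatures_reproducible_from_full_lp_engines(self):
        """complete() over naive and FR states yields identical signatures."""
        seq = random_sequence(30, 13)
        q = 2
        sig_sets = []
        for solver in (solve_naive, lambda s: solve_fr(s, q=q)):
            res = solver(seq)
            dp = res.dp
            dp.oct = np.zeros((31, 31), dtype=bool)
            dp.step = np.zeros((31, 31), dtype=bool)
            sigs = SigIndex(q=q)
            for j in range(2, 31):
                for g in range(j // q + 1):
                    complete(dp, sigs, j=j, g=g)
            sig_sets.append((sigs.sig_oct, sigs.sig_step))
        assert sig_sets[0] == sig_sets[1]


class TestGTable:
    def test_zero_signature_is_empty(self):
        assert GTable().lookup(3, 0, {}, OpCounters()) == ()

    def test_build_matches_brute_force_filter(self):
        rng = np.random.default_rng(5)
        sig_step = {(gp, 4): int(rng.integers(0, 16)) for gp in range(5)}
        gt = GTable()
        c = OpCounters()
        for m in range(1, 16):
            got = gt.lookup(4, m, sig_step, c)
            expect = tuple(gp for gp in range(5) if sig_step[(gp, 4)] & m)
            assert got == expect
        assert c.g_builds == 15

    def test_memoized_single_build(self):
        sig_step = {(0, 2): 0b11}
        gt = GTable()
        c = OpCounters()
        first = gt.lookup(2, 0b01, sig_step, c)
        second = gt.lookup(2, 0b01, sig_step, c)
        assert first == second == (0,)
        assert c.g_builds == 1


class TestSolveSfr:
    @pytest.mark.parametrize("n,seed", [(16, 1), (33, 2), (64, 3), (96, 4)])
    def test_matrix_equals_naive(self, n, seed):
        seq = random_sequence(n, seed)
        assert_same_L(solve_sfr(seq), solve_naive(seq))

    @pytest.mark.parametrize("q", [1, 2, 3])
    def test_explicit_block_sizes(self, q):
        seq = random_sequence(40, 17)
        assert_same_L(solve_sfr(seq, q=q), solve_naive(seq))

    def test_d3_scheme(self, d3_scheme):
        seq = random_sequence(40, 19)
        assert_same_L(
            solve_sfr(seq, scheme=d3_scheme, q=2),
            solve_naive(seq, scheme=d3_scheme),
        )

    def test_gate_disable_changes_counters_not_values(self):
        """Theorem-1 safety: gating only prunes provably useless lookups."""
        for n, seed in [(32, 5), (64, 6), (96, 7)]:
            seq = random_sequence(n, seed)
            gated = solve_sfr(seq)
            ungated = solve_sfr(seq, gated=False)
            assert np.array_equal(gated.dp.L, ungated.dp.L)
            gc, uc = gated.counters, ungated.counters
            assert gc.mul_builds + gc.mul_lookups <= uc.mul_builds + uc.mul_lookups

    @pytest.mark.parametrize("seed", range(5))
    def test_dominates_both_parents_at_n64(self, seed):
        """Counted operations never exceed the cheaper of SP and FR alone."""
        seq = random_sequence(64, 80 + seed)
        sfr = solve_sfr(seq, keep_dp=False).counters.total()
        sp = solve_sparse(seq, keep_dp=False).counters.total()
        fr = solve_fr(seq, keep_dp=False).counters.total()
        assert sfr <= min(sp, fr)

    def test_oct_flags_superset_of_unrestricted(self):
        """Restricted Lp can only promote cells into OCT, never out of it."""
        seq = random_sequence(48, 23)
        sfr = solve_sfr(seq)
        naive = solve_naive(seq)
        strict_oct = (naive.dp.L == naive.dp.Lc) & (naive.dp.Lc > naive.dp.Lp)
        assert (sfr.dp.oct | ~strict_oct).all()
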