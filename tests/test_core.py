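"""Domain types: sequence normalization, scoring, block grid, foldings."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnassf import (
    BlockGrid,
    Folding,
    RnaSequence,
    ScoringScheme,
    beta,
    choose_q,
    normalize_sequence,
    random_sequence,
    solve_naive,
)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [("gcgc", "GCGC"), ("ACGT", "ACGU"), ("  a c\ngu\t", "ACGU"), ("uuu", "UUU")],
    )
    def test_normalization(self, raw, expected):
        assert normalize_sequence(raw).residues == expected

    def test_invalid_symbol_position_reported(self):
        with pytest.raises(ValueError, match="position 3"):
            normalize_sequence("ACGN")

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_sequence("   \n")

    def test_substring_is_half_open(self):
        seq = normalize_sequence("ACGUA")
        assert seq.s(1, 4) == "CGU"
        assert seq.s(2, 2) == ""
        with pytest.raises(IndexError):
            seq.s(0, 6)


class TestScoring:
    @pytest.mark.parametrize(
        "a,b,score", [("G", "C", 1), ("C", "G", 1), ("A", "U", 1), ("A", "A", 0), ("G", "U", 0)]
    )
    def test_default_beta(self, default_scheme, a, b, score):
        assert beta(default_scheme, a, b) == score

    def test_default_discreteness_parameters(self, default_scheme):
        assert default_scheme.beta_max == 1
        assert default_scheme.D == 2

    def test_custom_scheme_symmetric_and_discrete(self, d3_scheme):
        assert d3_scheme.beta("C", "G") == d3_scheme.beta("G", "C") == 2
        assert d3_scheme.beta("U", "G") == 1
        assert d3_scheme.beta_max == 2
        assert d3_scheme.D == 3

    def test_negative_or_noninteger_scores_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme.from_pairs({"GC": -1})
        with pytest.raises(ValueError):
            ScoringScheme.from_pairs({"GC": 1.5})  # type: ignore[dict-item]


class TestChooseQ:
    @pytest.mark.parametrize(
        "n,eps,D,expected", [(256, 0.5, 2, 4), (16, 0.25, 2, 1), (4, 0.4, 2, 1), (128, 0.4, 2, 2)]
    )
    def test_values(self, n, eps, D, expected):
        assert choose_q(n, eps, D) == expected

    @pytest.mark.parametrize("eps", [0.0, -0.1, 0.51, 2.0])
    def test_epsilon_out_of_range(self, eps):
        with pytest.raises(ValueError):
            choose_q(64, eps, 2)

    def test_cap(self):
        assert choose_q(2**40, 0.5, 2, max_q=8) == 8


class TestBlockGrid:
    @given(n=st.integers(0, 200), q=st.integers(1, 9))
    @settings(max_examples=60, deadline=None)
    def test_groups_partition_indices(self, n, q):
        grid = BlockGrid(n, q)
        covered = [i for g in range(grid.n_groups) for i in grid.members(g)]
        assert covered == list(range(n + 1))
        for i in range(n + 1):
            assert i in grid.members(grid.group_of(i))

    def test_fullness(self):
        grid = BlockGrid(10, 4)
        assert grid.is_full(0) and grid.is_full(1)
        assert not grid.is_full(2)  # covers {8,9,10} only
        assert not grid.is_full(0, limit=3)


class TestFolding:
    def test_crossing_rejected(self):
        with pytest.raises(ValueError, match="crosses"):
            Folding.of([(0, 2), (1, 3)]).validate(4)

    def test_shared_position_rejected(self):
        with pytest.raises(ValueError, match="more than one"):
            Folding.of([(0, 2), (2, 3)]).validate(4)

    def test_nested_and_adjacent_ok(self):
        Folding.of([(0, 5), (1, 4), (2, 3), (6, 7)]).validate(8)

    def test_score(self, default_scheme):
        seq = RnaSequence("GCAU")
        assert Folding.of([(0, 1), (2, 3)]).score(seq, default_scheme) == 2


class TestColumnStructure:
    """Vertical monotonicity / discreteness of L columns (Observation-style)."""

    @pytest.mark.parametrize("n,seed", [(16, 3), (40, 5), (40, 9)])
    def test_default_scheme_columns_2_discrete(self, n, seed):
        L = solve_naive(random_sequence(n, seed)).dp.L
        for j in range(n + 1):
            col = L[: j + 1, j]
            d = col[:-1] - col[1:]
            assert (d >= 0).all() and (d <= 1).all()

    def test_d3_scheme_columns_3_discrete(self, d3_scheme):
        L = solve_naive(random_sequence(40, 11), scheme=d3_scheme).dp.L
        for j in range(41):
            col = L[: j + 1, j]
            d = col[:-1] - col[1:]
            assert (d >= 0).all() and (d <= d3_scheme.beta_max).all()
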