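"""Delta-encoding, block max-plus, encoded max, and table memoization."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnassf import (
    DeltaVector,
    MaxTable,
    MulTable,
    OpCounters,
    block_mul,
    delta_decode,
    delta_encode,
    delta_max,
)


class TestRoundTrip:
    @pytest.mark.parametrize(
        "v,D,expected",
        [
            ([5, 4, 4, 3], 2, (5, 0b101)),
            ([3, 3, 3, 3], 2, (3, 0)),
            ([2, 1, 0, 0], 2, (2, 0b110)),
            ([7], 2, (7, 0)),
            ([4, 2, 2, 1], 3, (4, 2 * 9 + 0 * 3 + 1)),
        ],
    )
    def test_encode_examples(self, v, D, expected):
        dv = delta_encode(v, D)
        assert (dv.x0, dv.delta) == expected

    @pytest.mark.parametrize(
        "x0,delta,q,expected",
        [(5, 5, 4, [5, 4, 4, 3]), (0, 0, 3, [0, 0, 0])],
    )
    def test_decode_examples(self, x0, delta, q, expected):
        assert delta_decode(DeltaVector(x0, delta, q, 2)) == expected

    def test_exhaustive_round_trip_2_discrete(self):
        """Every 2-discrete vector of length q <= 6 survives encode/decode."""
        for q in range(1, 7):
            for delta in range(2 ** (q - 1)):
                for x0 in (-3, 0, 7):
                    dv = DeltaVector(x0, delta, q, 2)
                    v = delta_decode(dv)
                    back = delta_encode(v, 2)
                    assert (back.x0, back.delta) == (x0, delta)

    @given(
        D=st.sampled_from([3, 4]),
        x0=st.integers(-10, 10),
        digits=st.lists(st.integers(0, 3), min_size=0, max_size=5),
    )
    @settings(max_examples=120, deadline=None)
    def test_random_d_discrete_round_trip(self, D, x0, digits):
        digits = [d % D for d in digits]
        v = [x0]
        for d in digits:
            v.append(v[-1] - d)
        dv = delta_encode(v, D)
        assert delta_decode(dv) == v

    def test_difference_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="digit"):
            delta_encode([0, 2], 2)  # difference -2
        with pytest.raises(ValueError, match="digit"):
            delta_encode([3, 1], 2)  # difference 2 with D=2

    def test_delta_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            DeltaVector(7, 2 ** (4 - 1), 4, 2)

    def test_scalar_add_shifts_first_element_only(self):
        dv = delta_encode([5, 4, 4, 3], 2)
        shifted = dv + 3
        assert (shifted.x0, shifted.delta) == (8, dv.delta)
        assert delta_decode(shifted) == [8, 7, 7, 6]


def _random_discrete_block(rng: np.random.Generator, q: int, D: int) -> list[list[int]]:
    """Block whose consecutive rows differ by [0, D-1] per column, like L."""
    bottom = rng.integers(0, 10, size=q)
    rows = [bottom]
    for _ in range(q - 1):
        rows.append(rows[-1] + rng.integers(0, D, size=q))
    rows.reverse()
    return [list(map(int, r)) for r in rows]


class TestBlockMul:
    def test_hand_example(self):
        out = block_mul([[0, 1], [0, 0]], DeltaVector(0, 0, 2, 2))
        assert delta_decode(out) == [1, 0]

    def test_zero_block_zero_vector(self):
        out = block_mul([[0, 0], [0, 0]], DeltaVector(0, 0, 2, 2))
        assert delta_decode(out) == [0, 0]

    @pytest.mark.parametrize("q", [2, 3, 4])
    @pytest.mark.parametrize("D", [2, 3])
    def test_matches_plain_max_plus_oracle(self, q, D):
        rng = np.random.default_rng(100 * q + D)
        for _ in range(250):
            block = _random_discrete_block(rng, q, D)
            digits = rng.integers(0, D, size=q - 1)
            vec = [0]
            for d in digits:
                vec.append(vec[-1] - int(d))
            dv = delta_encode(vec, D)
            got = delta_decode(block_mul(block, dv))
            expect = [max(block[r][c] + vec[c] for c in range(q)) for r in range(q)]
            assert got == expect


class TestDeltaMax:
    def test_gap_shortcut_returns_dominant_vector(self):
        v = delta_encode([2, 1, 1], 2)
        w = delta_encode([6, 5, 4], 2)
        out = delta_max(v, w, MaxTable(), OpCounters())
        assert delta_decode(out) == [6, 5, 4]

    def test_hand_example(self):
        v = delta_encode([2, 2, 1], 2)
        w = delta_encode([3, 2, 2], 2)
        out = delta_max(v, w, MaxTable(), OpCounters())
        assert delta_decode(out) == [3, 2, 2]

    def test_idempotent(self):
        v = delta_encode([4, 3, 3], 2)
        assert delta_decode(delta_max(v, v, MaxTable(), OpCounters())) == [4, 3, 3]

    def test_exhaustive_q3_matches_elementwise_oracle(self):
        """All 2-discrete q=3 vector pairs with offsets 0..4."""
        table = MaxTable()
        c = OpCounters()
        for da, db in itertools.product(range(4), repeat=2):
            for off in range(5):
                a = delta_decode(DeltaVector(0, da, 3, 2))
                b = delta_decode(DeltaVector(off, db, 3, 2))
                got = delta_decode(
                    delta_max(delta_encode(a, 2), delta_encode(b, 2), table, c)
                )
                assert got == [max(x, y) for x, y in zip(a, b)]
        # entry count bound: D^(q-1) * D^(q-1) * ((q-1)(D-1)+1) at D=2, q=3
        assert len(table) <= 4 * 4 * 3

    def test_d3_threshold_uses_d_discrete_bound(self):
        """With D=3 an offset of q-1 no longer implies dominance."""
        v = delta_encode([4, 4, 4], 3)  # constant
        w = delta_encode([6, 4, 2], 3)  # drops by 2 per step; w0 - v0 = 2 = q-1
        out = delta_decode(delta_max(v, w, MaxTable(), OpCounters()))
        assert out == [6, 4, 4]


class TestMulTableMemoization:
    def test_build_once_then_hit(self):
        table = MulTable()
        c = OpCounters()
        block = [[0, 1], [0, 0]]
        first = table.access(0, 1, 0, 2, 2, lambda gp, g: block, c)
        second = table.access(0, 1, 0, 2, 2, lambda gp, g: block, c)
        assert first == second
        assert (c.mul_builds, c.mul_lookups) == (1, 1)
        assert table.entries_per_block[(0, 1)] == 1

    def test_entries_per_block_bounded(self):
        table = MulTable()
        c = OpCounters()
        block = [[3, 2], [2, 2]]
        for delta in range(2):
            table.access(0, 1, delta, 2, 2, lambda gp, g: block, c)
        assert table.max_entries_per_block() <= 2 ** (2 - 1)
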