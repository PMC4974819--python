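"""Delta-encoded vectors and the on-demand MUL / MAX lookup tables.

The Four-Russians speedup rests on one observation: appending a single
nucleotide changes the optimum by at most the best single pair score, so
consecutive entries of any column of L differ by a value in [0, beta_max].
A length-q slice of such a *D-discrete* vector (D = beta_max + 1) is fully
described by its first element ``x0`` plus the base-D integer ``delta`` of
its q-1 consecutive differences, first difference most significant.  Adding
a constant shifts ``x0`` only, so the q-element max-plus product and the
q-element elementwise max can be memoized keyed by differences alone:

* ``MUL[(g', g, delta)]`` caches  B (x) (0, delta)  for the finalized q x q
  block B = L[I_g', K_g], where (x) is row-wise max-plus.  At most D^(q-1)
  entries exist per block.
* ``MAX[(dv, dw, h)]`` caches  max((0, dv), (h, dw))  for first-element
  offsets h up to (q-1)(D-1); beyond that offset the higher vector dominates
  elementwise and no table entry is needed.  (For the 2-discrete case this
  threshold is the familiar q-1.)

Both tables are built lazily, entry by entry, the first time a computation
actually needs them, and every entry is immutable once written.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence, Tuple

from .core import OpCounters


@dataclass(frozen=True)
class DeltaVector:
    """Delta-encoding (x0, delta) of a D-discrete vector of length q."""

    x0: int
    delta: int
    q: int
    D: int

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.D < 2:
            raise ValueError("D must be >= 2")
        if not (0 <= self.delta < self.D ** (self.q - 1)):
            raise ValueError(
                f"delta {self.delta} out of range [0, {self.D ** (self.q - 1)}) "
                f"for q={self.q}, D={self.D}"
            )

    def decode(self) -> List[int]:
        return delta_decode(self)

    def __add__(self, c: int) -> "DeltaVector":
        """Adding a constant to every element shifts x0 only."""
        return DeltaVector(self.x0 + c, self.delta, self.q, self.D)


def delta_encode(v: Sequence[int], D: int) -> DeltaVector:
    """Encode a D-discrete vector; differences must be base-D digits.

    ``delta`` packs the differences [v0-v1, v1-v2, ...] MSB-first in base D.
    A difference outside [0, D-1] (in particular a negative one: encodable
    vectors are non-increasing) is rejected.
    """
    q = len(v)
    if q < 1:
        raise ValueError("cannot encode an empty vector")
    delta = 0
    for l in range(1, q):
        d = v[l - 1] - v[l]
        if not (0 <= d < D):
            raise ValueError(
                f"difference {d} at position {l} is not a base-{D} digit"
            )
        delta = delta * D + d
    return DeltaVector(int(v[0]), delta, q, D)


def delta_decode(dv: DeltaVector) -> List[int]:
    """Inverse of :func:`delta_encode` (range-checked by DeltaVector)."""
    digits = []
    rem = dv.delta
    for _ in range(dv.q - 1):
        rem, d = divmod(rem, dv.D)
        digits.append(d)
    digits.reverse()  # MSB-first: first difference applies first
    out = [dv.x0]
    for d in digits:
        out.append(out[-1] - d)
    return out


def block_mul(block: Sequence[Sequence[int]], dv: DeltaVector) -> DeltaVector:
    """Row-wise max-plus product of a q x q block with a decoded vector.

    result[r] = max_c (block[r][c] + x[c]).  Direct O(q^2) evaluation; the
    result is again D-discrete (consecutive block rows differ by [0, D-1]
    per column), so it Delta-encodes.
    """
    x = dv.decode()
    q = dv.q
    if len(block) != q or any(len(row) != q for row in block):
        raise ValueError(f"block must be {q}x{q}")
    y = [max(row[c] + x[c] for c in range(q)) for row in block]
    return delta_encode(y, dv.D)


class MulTable:
    """On-demand cache of block max-plus products, keyed (g', g, delta)."""

    def __init__(self) -> None:
        self._entries: Dict[Tuple[int, int, int], DeltaVector] = {}
        self.entries_per_block: Dict[Tuple[int, int], int] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def access(
        self,
        gp: int,
        g: int,
        delta: int,
        q: int,
        D: int,
        block_provider: Callable[[int, int], Sequence[Sequence[int]]],
        counters: OpCounters,
    ) -> DeltaVector:
        """Cached MUL entry, building it on first demand.

        ``block_provider(g', g)`` must return the finalized block; it is only
        called on a build.  Hits count as ``mul_lookups``, builds as
        ``mul_builds``; cold and warm queries return the identical vector.
        """
        key = (gp, g, delta)
        hit = self._entries.get(key)
        if hit is not None:
            counters.mul_lookups += 1
            return hit
        y = block_mul(block_provider(gp, g), DeltaVector(0, delta, q, D))
        self._entries[key] = y
        self.entries_per_block[(gp, g)] = self.entries_per_block.get((gp, g), 0) + 1
        counters.mul_builds += 1
        return y

    def max_entries_per_block(self) -> int:
        return max(self.entries_per_block.values(), default=0)


class MaxTable:
    """On-demand cache of offset elementwise maxima, keyed (dv, dw, h)."""

    def __init__(self) -> None:
        self._entries: Dict[Tuple[int, int, int], DeltaVector] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def get_or_build(self, dv: int, dw: int, h: int, q: int, D: int, counters: OpCounters) -> DeltaVector:
        key = (dv, dw, h)
        hit = self._entries.get(key)
        if hit is not None:
            counters.max_lookups += 1
            return hit
        a = DeltaVector(0, dv, q, D).decode()
        b = DeltaVector(h, dw, q, D).decode()
        z = [x if x >= y else y for x, y in zip(a, b)]
        out = delta_encode(z, D)
        self._entries[key] = out
        counters.max_builds += 1
        return out


def delta_max(v: DeltaVector, w: DeltaVector, table: MaxTable, counters: OpCounters) -> DeltaVector:
    """Elementwise max of two encoded vectors via the MAX table.

    With w0 >= v0 (swap otherwise): when the offset h = w0 - v0 exceeds
    (q-1)(D-1), w dominates elementwise and is returned after a single O(1)
    scalar comparison -- no table is touched, so no table event is counted;
    otherwise the answer is MAX[dv, dw, h] + v0, building the table entry on
    demand in O(q).
    """
    if v.q != w.q or v.D != w.D:
        raise ValueError("delta_max operands must share q and D")
    if w.x0 < v.x0:
        v, w = w, v
    h = w.x0 - v.x0
    if h > (v.q - 1) * (v.D - 1):
        return w
    return table.get_or_build(v.delta, w.delta, h, v.q, v.D, counters) + v.x0
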