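"""Sparsified folding via STEP/OCT candidate lists.

Two structural properties drive the pruning.  A cell (i, j) is *OCT*
(optimally co-terminus) when L[i,j] = Lc[i,j] > Lp[i,j]: every optimal
folding of s_{i,j} pairs its ends.  It is *STEP* when L[i,j] > L[i+1,j]:
position i is paired in every optimal folding.  The candidate-list theorem
for this DP states that every cell has an optimal split point k that is
either the mandatory k = i+1 or satisfies "(i,k) is STEP and (k,j) is OCT" --
so only those k need be examined.

The engine keeps, per finished column, the list of its STEP rows; while a
column j is being filled (rows descending) each newly classified OCT cell
(k, j) immediately pushes the candidate k into Lp[i, j] for every STEP row i
of column k.  List maintenance is O(1) amortized per cell.  Candidate
evaluations (mandatory plus STEP-OCT) are what ``split_comparisons`` counts.

With pruning off (``debug_full=True``) every split point is evaluated, which
must not change any L value -- the soundness check for the candidate sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .core import (
    NEG_INF,
    BlockGrid,
    DpState,
    OpCounters,
    RnaSequence,
    ScoringScheme,
    SolveResult,
    base_indices,
)


@dataclass
class SparsityIndex:
    """Per-column OCT and STEP row lists plus their totals.

    ``oct_rows_by_column[j]`` holds the rows k with cell (k, j) OCT, and
    ``step_rows_by_column[k]`` the rows i with cell (i, k) STEP, both in
    ascending order.  ``Z`` is the total OCT count (bounded by n^2/2) and
    ``step_count_by_column[k]`` is bounded by beta_max * floor(k/2), since
    STEP differences telescope to L[0, k].
    """

    n: int
    oct_rows_by_column: List[List[int]] = field(default_factory=list)
    step_rows_by_column: List[List[int]] = field(default_factory=list)
    Z: int = 0

    def __post_init__(self) -> None:
        if not self.oct_rows_by_column:
            self.oct_rows_by_column = [[] for _ in range(self.n + 1)]
        if not self.step_rows_by_column:
            self.step_rows_by_column = [[] for _ in range(self.n + 1)]

    @property
    def step_count_by_column(self) -> List[int]:
        return [len(rows) for rows in self.step_rows_by_column]


def classify_cell(dp: DpState, i: int, j: int) -> Tuple[bool, bool]:
    """(is_oct, is_step) for a finalized cell, from the matrices alone.

    Base cells (j <= i+1) are neither OCT nor STEP by convention: they score
    0, and for j = i+1 the STEP comparand L[i+1, i+1] is also 0.  Querying a
    cell that has not been finalized (sentinel in L) is a hard failure.
    """
    n = dp.n
    if not (0 <= i <= j <= n):
        raise IndexError(f"cell ({i},{j}) outside the upper triangle for n={n}")
    if int(dp.L[i, j]) == NEG_INF:
        raise RuntimeError(f"cell ({i},{j}) queried before finalization")
    if j <= i + 1:
        return (False, False)
    if int(dp.L[i + 1, j]) == NEG_INF:
        raise RuntimeError(f"cell ({i + 1},{j}) queried before finalization")
    lij, lp, lc = int(dp.L[i, j]), int(dp.Lp[i, j]), int(dp.Lc[i, j])
    is_oct = lij == lc and lc > lp
    is_step = lij > int(dp.L[i + 1, j])
    return (is_oct, is_step)


def solve_sparse(
    seq: RnaSequence,
    scheme: Optional[ScoringScheme] = None,
    min_loop: int = 0,
    keep_dp: bool = True,
    debug_full: bool = False,
) -> SolveResult:
    """Solve SSF examining only mandatory and STEP-OCT split points."""
    scheme = scheme or ScoringScheme.default()
    n = seq.n
    bt = scheme.beta_table().tolist()
    ix = base_indices(seq).tolist()
    bmax = scheme.beta_max

    L = [[NEG_INF] * (n + 1) for _ in range(n + 1)]
    Lp = [[NEG_INF] * (n + 1) for _ in range(n + 1)]
    Lc = [[NEG_INF] * (n + 1) for _ in range(n + 1)]
    octf = [[False] * (n + 1) for _ in range(n + 1)]
    stepf = [[False] * (n + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        L[i][i] = 0
        if i < n:
            L[i][i + 1] = 0

    idx = SparsityIndex(n)
    oct_cols = idx.oct_rows_by_column
    step_cols = idx.step_rows_by_column
    split = 0
    z_total = 0

    for j in range(2, n + 1):
        for k in range(j - 1, -1, -1):
            if k <= j - 2:
                # mandatory split point k' = i+1 for this cell (value L[k+1, j])
                best = L[k + 1][j]
                split += 1
                if Lp[k][j] > best:
                    best = Lp[k][j]
                Lp[k][j] = best
                lc = L[k + 1][j - 1] + bt[ix[k]][ix[j - 1]] if (j - 1 - k) > min_loop else NEG_INF
                Lc[k][j] = lc
                lkj = best if best >= lc else lc
                L[k][j] = lkj
                is_oct = lkj == lc and lc > best
                is_step = lkj > L[k + 1][j]
            else:
                is_oct = is_step = False
            if is_step:
                stepf[k][j] = True
                step_cols[j].append(k)
            if is_oct:
                octf[k][j] = True
                oct_cols[j].append(k)
                z_total += 1
            if debug_full:
                if 1 <= k <= j - 1:
                    lkj = L[k][j]
                    for i in range(k):
                        cand = L[i][k] + lkj
                        split += 1
                        if cand > Lp[i][j]:
                            Lp[i][j] = cand
            elif is_oct or k == j - 1:
                # k = j-1 is a candidate for every cell: the single-nucleotide
                # sub-instance s_{j-1,j} is vacuously co-terminus (it has no
                # split point at all), even though the strict matrix test
                # L = Lc > Lp cannot flag it.
                lkj = L[k][j]
                for i in step_cols[k]:
                    cand = L[i][k] + lkj
                    split += 1
                    if cand > Lp[i][j]:
                        Lp[i][j] = cand
        step_cols[j].reverse()
        oct_cols[j].reverse()
        assert len(step_cols[j]) <= max(1, bmax) * (j // 2), (
            f"STEP count {len(step_cols[j])} in column {j} exceeds its bound"
        )
    idx.Z = z_total
    assert z_total <= n * n / 2, f"Z = {z_total} exceeds n^2/2"

    dp = DpState(
        L=np.array(L, dtype=np.int64),
        Lp=np.array(Lp, dtype=np.int64),
        Lc=np.array(Lc, dtype=np.int64),
        grid=BlockGrid(n, 1),
        oct=np.array(octf, dtype=bool),
        step=np.array(stepf, dtype=bool),
    )
    counters = OpCounters(split_comparisons=split)
    return SolveResult(
        score=int(L[0][n]),
        engine="sp",
        counters=counters,
        dp=dp if keep_dp else None,
        params={"min_loop": min_loop, "Z": z_total, "debug_full": debug_full},
    )
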