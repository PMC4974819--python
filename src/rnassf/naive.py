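"""Baseline O(n^3) folding DP and an exhaustive brute-force oracle.

The recurrence, for j > i + 1 over half-open subsequences s_{i,j}:

    L[i, j]  = max(Lp[i, j], Lc[i, j])
    Lp[i, j] = max_{i < k < j} (L[i, k] + L[k, j])      (partitioned)
    Lc[i, j] = L[i+1, j-1] + beta(s_i, s_{j-1})         (co-terminus)

with L[i, i] = L[i, i+1] = 0.  Matrices are traversed in increasing column
order j, and within a column in decreasing row order k; once L[k, j] is
final it is pushed into Lp[i, j] for every i < k.  Each such push of one
candidate split point counts as one split comparison, so the counter totals
exactly C(n+1, 3) -- the quantity the operation-count benchmark reports for
this engine.  Evaluating Lc and the final two-way max are not counted.
"""

from __future__ import annotations

from typing import Optional

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

BRUTE_FORCE_MAX_N = 16


def init_matrices(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fresh (n+1)x(n+1) L/Lp/Lc filled with the sentinel; L base cases set."""
    L = np.full((n + 1, n + 1), NEG_INF, dtype=np.int64)
    Lp = np.full((n + 1, n + 1), NEG_INF, dtype=np.int64)
    Lc = np.full((n + 1, n + 1), NEG_INF, dtype=np.int64)
    idx = np.arange(n + 1)
    L[idx, idx] = 0
    L[idx[:-1], idx[:-1] + 1] = 0
    return L, Lp, Lc


def solve_naive(
    seq: RnaSequence,
    scheme: Optional[ScoringScheme] = None,
    min_loop: int = 0,
    keep_dp: bool = True,
) -> SolveResult:
    """Solve SSF by the unsparsified cubic DP.

    ``min_loop`` is the minimum number of unpaired positions required between
    the two ends of a pair; 0 (the default) allows adjacent positions to pair.
    """
    scheme = scheme or ScoringScheme.default()
    n = seq.n
    L, Lp, Lc = init_matrices(n)
    counters = OpCounters()
    if n >= 2:
        ix = base_indices(seq)
        bt = scheme.beta_table()
        split = 0
        for j in range(2, n + 1):
            # co-terminus scores for the whole column: pair (i, j-1) allowed
            # when it spans more than min_loop unpaired positions.
            top = max(0, j - 1 - min_loop)
            if top > 0:
                Lc[0:top, j] = L[1 : top + 1, j - 1] + bt[ix[0:top], ix[j - 1]]
            for k in range(j - 1, 0, -1):
                if k <= j - 2:
                    L[k, j] = max(Lp[k, j], Lc[k, j])
                # push finalized L[k, j] as split point k into all rows above
                Lp[0:k, j] = np.maximum(Lp[0:k, j], L[0:k, k] + L[k, j])
                split += k
            L[0, j] = max(Lp[0, j], Lc[0, j])
        counters.split_comparisons = split
    dp = DpState(L=L, Lp=Lp, Lc=Lc, grid=BlockGrid(n, 1))
    return SolveResult(
        score=int(L[0, n]),
        engine="naive",
        counters=counters,
        dp=dp if keep_dp else None,
        params={"min_loop": min_loop},
    )


def brute_force_score(
    seq: RnaSequence, scheme: Optional[ScoringScheme] = None, min_loop: int = 0
) -> int:
    """Maximum folding score by explicit recursive enumeration.

    Enumerates every non-crossing matching (position i is left unpaired, or
    paired with each admissible l in turn), with no memoization, so the result
    is independent of the DP code paths it serves as an oracle for.  Guarded
    to n <= 16 because the number of matchings grows exponentially.
    """
    scheme = scheme or ScoringScheme.default()
    n = seq.n
    if n > BRUTE_FORCE_MAX_N:
        raise ValueError(f"brute force limited to n <= {BRUTE_FORCE_MAX_N}, got {n}")
    res = seq.residues

    def best(i: int, j: int) -> int:
        if j - i < 2:
            return 0
        b = best(i + 1, j)  # i unpaired
        for l in range(i + 1, j):
            if l - i > min_loop:
                b = max(b, scheme.beta(res[i], res[l]) + best(i + 1, l) + best(l + 1, j))
        return b

    return best(0, n)
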