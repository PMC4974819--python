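"""On-demand Four-Russians folding engine.

The matrix is tiled into q x q blocks and q-row subcolumns (Kgroups).  Within
a column j, subvectors are finalized from the group containing j downward.
Whenever the subvector L[K_g, j] becomes full it is Delta-encoded once, and
for every row group I_g' below it the partitioned-score contribution

    Lp[I_g', j]  <-  max(Lp[I_g', j], MUL[L[I_g', K_g]](delta) + L[gq, j])

is folded into a running encoded accumulator with ``delta_max``.  Each
accumulator is decoded back into the Lp cells exactly once, just before its
own row group's cells are finished.  Split points that do not fall in a full
Kgroup -- those inside the cell's own group, those in the partial group
containing j, and the mandatory k = i+1 -- are evaluated cell by cell and
counted as split comparisons; table traffic is counted separately.

Block size defaults to q = floor(epsilon * log_D n) with epsilon = 0.4,
capped at 8; q = 1 degenerates to the plain cubic traversal where every
split point is one (cached) 1 x 1 table access.
"""

from __future__ import annotations

from typing import List, Optional

from ._dp import init_lists, to_state
from .core import (
    NEG_INF,
    BlockGrid,
    OpCounters,
    RnaSequence,
    ScoringScheme,
    SolveResult,
    base_indices,
    choose_q,
)
from .encoding import DeltaVector, MaxTable, MulTable, delta_max


def solve_fr(
    seq: RnaSequence,
    scheme: Optional[ScoringScheme] = None,
    epsilon: float = 0.4,
    q: Optional[int] = None,
    min_loop: int = 0,
    max_q: int = 8,
    keep_dp: bool = True,
) -> SolveResult:
    """Solve SSF with the on-demand Four-Russians block speedup.

    ``q`` overrides the epsilon-derived block size (useful for exercising
    D-discrete schemes at modest n, where epsilon*log_D n rounds to 1).
    """
    scheme = scheme or ScoringScheme.default()
    n = seq.n
    D = scheme.D
    if q is None:
        q = choose_q(n, epsilon, D, max_q) if n >= 1 else 1
    grid = BlockGrid(max(n, 0), q)
    L, Lp, Lc = init_lists(n)
    counters = OpCounters()
    mul = MulTable()
    maxt = MaxTable()

    if n >= 2:
        ix = base_indices(seq).tolist()
        bt = scheme.beta_table().tolist()

        def provider(gp: int, g: int) -> List[List[int]]:
            rlo, clo = q * gp, q * g
            return [L[r][clo : clo + q] for r in range(rlo, rlo + q)]

        split = 0
        for j in range(2, n + 1):
            gj = j // q
            acc: List[Optional[DeltaVector]] = [None] * (gj + 1)
            bj = bt[ix[j - 1]]
            tstart = q * gj
            for g in range(gj, -1, -1):
                lo = q * g
                a = acc[g]
                if a is not None:
                    vals = a.decode()
                    for t in range(q):
                        Lp[lo + t][j] = vals[t]
                for i in range(min(lo + q - 1, j - 2), lo - 1, -1):
                    Li = L[i]
                    best = Lp[i][j]
                    if g == gj:
                        for k in range(i + 1, j):
                            cand = Li[k] + L[k][j]
                            split += 1
                            if cand > best:
                                best = cand
                    else:
                        pend = lo + q
                        for k in range(i + 1, pend):
                            cand = Li[k] + L[k][j]
                            split += 1
                            if cand > best:
                                best = cand
                        if tstart < j:
                            for k in range(tstart, j):
                                cand = Li[k] + L[k][j]
                                split += 1
                                if cand > best:
                                    best = cand
                        if i + 1 == pend and pend < tstart:
                            # mandatory split point, always examined per-cell
                            cand = L[i + 1][j]
                            split += 1
                            if cand > best:
                                best = cand
                    Lp[i][j] = best
                    lc = L[i + 1][j - 1] + bj[ix[i]] if (j - 1 - i) > min_loop else NEG_INF
                    Lc[i][j] = lc
                    L[i][j] = best if best >= lc else lc
                if lo + q <= j and g >= 1:
                    # subvector is full: encode and push into all lower groups
                    x0 = L[lo][j]
                    delta = 0
                    prev = x0
                    for r in range(lo + 1, lo + q):
                        cur = L[r][j]
                        delta = delta * D + (prev - cur)
                        prev = cur
                    for gp in range(g):
                        y = mul.access(gp, g, delta, q, D, provider, counters)
                        contrib = y + x0
                        a2 = acc[gp]
                        acc[gp] = (
                            contrib if a2 is None else delta_max(a2, contrib, maxt, counters)
                        )
        counters.split_comparisons = split

    assert mul.max_entries_per_block() <= D ** (q - 1), (
        "MUL table exceeded its per-block entry bound"
    )
    return SolveResult(
        score=int(L[0][n]),
        engine="fr",
        counters=counters,
        dp=to_state(L, Lp, Lc, grid) if keep_dp else None,
        params={
            "q": q,
            "epsilon": epsilon,
            "min_loop": min_loop,
            "mul_entries": len(mul),
            "max_entries": len(maxt),
        },
    )
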