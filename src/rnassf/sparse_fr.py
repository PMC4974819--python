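"""Sparse Four-Russians engine: signature-gated block lookups.

Combines the block/table machinery of the Four-Russians engine with the
STEP/OCT pruning of the sparsified engine.  Two kinds of q-bit signatures
summarize where the sparsity lives:

* ``sigOct(g, j)``  -- bit x set iff cell (qg+x, j) is OCT;
* ``sigStep(g', g)`` -- bit x set iff some row of block L[I_g', K_g] is STEP
  in column qg+x.

Every optimal split point k for (i, j) is either the mandatory i+1 or has
(i,k) STEP and (k,j) OCT, so a MUL access for block (g', g) against the
subvector L[K_g, j] can only matter when the bitwise dot product
sigStep(g', g) . sigOct(g, j) is 1.  The on-demand G table maps
(column group g, signature m) to the row groups passing that test, so each
full subvector touches only the blocks that can still change the optimum.
Cell-by-cell work (the partial group containing j and the cell's own group)
follows the sparsified candidate iteration: mandatory k = i+1 plus STEP-OCT
rows only.

Setting ``gated=False`` bypasses the signature test (every lower row group
is updated, as in the plain Four-Russians engine) while keeping the
sparsified per-cell iteration; by the gating theorem this may only change
counters, never a matrix value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from ._dp import init_lists, to_state
from .core import (
    NEG_INF,
    BlockGrid,
    DpState,
    OpCounters,
    RnaSequence,
    ScoringScheme,
    SolveResult,
    base_indices,
    choose_q,
)
from .encoding import DeltaVector, MaxTable, MulTable, delta_max
from .sparse import classify_cell


def sig_dot(m: int, mp: int) -> int:
    """Boolean dot product of two bit signatures: 1 iff they share a set bit."""
    return 1 if (m & mp) else 0


@dataclass
class SigIndex:
    """OCT-subcolumn and STEP-submatrix signatures for a block grid.

    ``sig_oct[(g, j)]`` and ``sig_step[(g', g)]`` are q-bit integers; bit
    position x (offset within the Kgroup) carries value 2**x.  Missing keys
    mean an all-zero signature.
    """

    q: int
    sig_oct: Dict[Tuple[int, int], int] = field(default_factory=dict)
    sig_step: Dict[Tuple[int, int], int] = field(default_factory=dict)


def complete(dp: DpState, sigs: SigIndex, j: int, g: int) -> Tuple[int, List[int]]:
    """Tabulate OCT/STEP status and signatures for subvector L[K_g, j].

    Classifies each finalized cell of the subvector, records the flags in the
    DP state, stores ``sig_oct(g, j)``, and folds any STEP cells of column j
    into ``sig_step(row group, column group of j)``.  Returns the OCT
    signature and the STEP rows found.  Pure function of the DP state, so
    signatures are reproducible across engines that agree on L/Lp/Lc.
    """
    q = sigs.q
    n = dp.n
    if dp.oct is None or dp.step is None:
        raise ValueError("DP state lacks oct/step flag arrays")
    m = 0
    step_rows: List[int] = []
    gj = j // q
    for x in range(q):
        r = q * g + x
        if r > min(n, j):
            break
        is_oct, is_step = classify_cell(dp, r, j)
        dp.oct[r, j] = is_oct
        dp.step[r, j] = is_step
        if is_oct:
            m |= 1 << x
        if is_step:
            step_rows.append(r)
            key = (r // q, gj)
            sigs.sig_step[key] = sigs.sig_step.get(key, 0) | (1 << (j - q * gj))
    sigs.sig_oct[(g, j)] = m
    return m, step_rows


class GTable:
    """On-demand map (column group g, signature m) -> gated row groups."""

    def __init__(self) -> None:
        self._entries: Dict[Tuple[int, int], Tuple[int, ...]] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def lookup(
        self,
        g: int,
        m: int,
        sig_step: Dict[Tuple[int, int], int],
        counters: OpCounters,
    ) -> Tuple[int, ...]:
        """Row groups g' <= g with sigStep(g', g) . m = 1.

        Cached per (g, m); a miss scans the row groups with a nonzero STEP
        signature for column group g (one word-AND each) and counts one
        ``g_builds`` event.  Cache hits re-verify membership against the live
        signatures -- the STEP signatures of a completed column group are
        immutable, so this must always pass.
        """
        if m == 0:
            return ()
        key = (g, m)
        hit = self._entries.get(key)
        if hit is not None:
            assert all(sig_dot(sig_step.get((gp, g), 0), m) == 1 for gp in hit), (
                "cached G entry contradicts live STEP signatures"
            )
            return hit
        built = tuple(
            gp for gp in range(g + 1) if sig_step.get((gp, g), 0) & m
        )
        self._entries[key] = built
        counters.g_builds += 1
        return built


def solve_sfr(
    seq: RnaSequence,
    scheme: Optional[ScoringScheme] = None,
    epsilon: float = 0.4,
    q: Optional[int] = None,
    min_loop: int = 0,
    max_q: int = 8,
    keep_dp: bool = True,
    gated: bool = True,
) -> SolveResult:
    """Solve SSF with signature-gated Four-Russians block computation."""
    scheme = scheme or ScoringScheme.default()
    n = seq.n
    D = scheme.D
    if q is None:
        q = choose_q(n, epsilon, D, max_q) if n >= 1 else 1
    grid = BlockGrid(max(n, 0), q)
    L, Lp, Lc = init_lists(n)
    octf = [[False] * (n + 1) for _ in range(n + 1)]
    stepf = [[False] * (n + 1) for _ in range(n + 1)]
    counters = OpCounters()
    mul = MulTable()
    maxt = MaxTable()
    gtab = GTable()
    sig_oct: Dict[Tuple[int, int], int] = {}
    sig_step: Dict[Tuple[int, int], int] = {}

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
            col_oct = [False] * (j + 1)  # OCT flags of column j, filled as rows finish
            tail_oct: List[int] = []  # OCT rows in [q*gj, j), descending
            for g in range(gj, -1, -1):
                lo = q * g
                a = acc[g]
                if a is not None:
                    vals = a.decode()
                    for t in range(q):
                        Lp[lo + t][j] = vals[t]
                m_sub = 0
                for i in range(min(lo + q - 1, j - 2), lo - 1, -1):
                    Li = L[i]
                    stepi = stepf[i]
                    best = Lp[i][j]
                    # mandatory split point, always evaluated per-cell
                    cand = L[i + 1][j]
                    split += 1
                    if cand > best:
                        best = cand
                    # k = j-1: s_{j-1,j} is vacuously co-terminus (no split
                    # point exists for it), so it joins the candidates of
                    # every STEP row even though it is never strictly OCT.
                    # Evaluated here when row j-1 falls in this cell's
                    # per-cell region (tail or own group); when it lies in a
                    # full Kgroup the gating signature carries its bit.
                    jm1 = j - 1
                    if jm1 > i + 1 and (jm1 >= tstart or jm1 < lo + q) and stepi[jm1]:
                        cand = Li[jm1]  # + L[j-1][j] = 0
                        split += 1
                        if cand > best:
                            best = cand
                    if g == gj:
                        # whole remaining range is this cell's own (partial) group
                        for k in tail_oct:
                            if stepi[k]:
                                cand = Li[k] + L[k][j]
                                split += 1
                                if cand > best:
                                    best = cand
                    else:
                        for k in range(i + 2, lo + q):  # own-group prefix; i+1 never STEP
                            if col_oct[k] and stepi[k]:
                                cand = Li[k] + L[k][j]
                                split += 1
                                if cand > best:
                                    best = cand
                        for k in tail_oct:
                            if stepi[k]:
                                cand = Li[k] + L[k][j]
                                split += 1
                                if cand > best:
                                    best = cand
                    Lp[i][j] = best
                    lc = L[i + 1][j - 1] + bj[ix[i]] if (j - 1 - i) > min_loop else NEG_INF
                    Lc[i][j] = lc
                    lij = best if best >= lc else lc
                    L[i][j] = lij
                    # immediate classification (staged part of `complete`)
                    if lij == lc and lc > best:
                        octf[i][j] = True
                        col_oct[i] = True
                        m_sub |= 1 << (i - lo)
                        if g == gj:
                            tail_oct.append(i)
                    if lij > L[i + 1][j]:
                        stepf[i][j] = True
                        key = (i // q, gj)
                        sig_step[key] = sig_step.get(key, 0) | (1 << (j - tstart))
                if lo + q <= j and g >= 1:
                    # subvector full: record its OCT signature, then gate.
                    # The gating signature additionally carries the vacuous
                    # co-terminus bit for the base row j-1 when this group
                    # ends exactly at j.
                    sig_oct[(g, j)] = m_sub
                    m_gate = m_sub | ((1 << (q - 1)) if lo + q == j else 0)
                    if not gated:
                        groups = range(g)
                    elif m_gate:
                        groups = (gp for gp in gtab.lookup(g, m_gate, sig_step, counters) if gp < g)
                    else:
                        groups = ()
                    if gated and not m_gate:
                        continue
                    x0 = L[lo][j]
                    delta = 0
                    prev = x0
                    for r in range(lo + 1, lo + q):
                        cur = L[r][j]
                        delta = delta * D + (prev - cur)
                        prev = cur
                    for gp in groups:
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
    sigs = SigIndex(q=q, sig_oct=sig_oct, sig_step=sig_step)
    dp = to_state(L, Lp, Lc, grid, octf, stepf) if keep_dp else None
    return SolveResult(
        score=int(L[0][n]),
        engine="sfr",
        counters=counters,
        dp=dp,
        params={
            "q": q,
            "epsilon": epsilon,
            "min_loop": min_loop,
            "gated": gated,
            "sigs": sigs,
            "g_entries": len(gtab),
        },
    )
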