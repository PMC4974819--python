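"""Deterministic simulation of the per-column parallel folding algorithm.

One logical process per column.  In synchronous round d every still-active
column j computes the subvector L[I_{g_j - d}, j]: round 0 finishes the
partial group containing j, and each later round moves one row group up, so
column j takes g_j + 1 rounds in total.  A task pulls, for every full Kgroup
strictly between its row group and g_j, the block contribution through the
shared on-demand MUL/MAX tables, then finishes its cells exactly as the
serial Four-Russians engine does.  With ``sparsified=True`` the MUL access
for a (row group, Kgroup) pair is skipped unless the STEP/OCT signature dot
product passes, which can only remove work.

This simulates the dependency structure, not true concurrency: rounds
execute serially, and within a round columns run left to right.  Before a
task runs, every task whose cells it reads is asserted to have finalized in
an earlier round or -- for the streaming reads of the current antidiagonal
(the co-terminus cell in column j-1 and the tail/own-group cells of columns
left of j) -- in the same round by a smaller column.  Table builds are
charged to the first (lowest-index) column that demands the entry.
Per-column operation totals are the simulated cost model; the makespan is
their maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

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
from .sparse_fr import sig_dot


@dataclass
class RoundSchedule:
    """Record of the simulated execution: who computed what, and when."""

    q: int
    rounds: List[List[Tuple[int, int]]] = field(default_factory=list)  # (column, row group)
    ops_by_column: Dict[int, int] = field(default_factory=dict)
    rounds_by_column: Dict[int, int] = field(default_factory=dict)
    oct_by_column: Dict[int, int] = field(default_factory=dict)  # Z_j

    @property
    def makespan(self) -> int:
        """Largest per-column operation total (simulated parallel cost)."""
        return max(self.ops_by_column.values(), default=0)

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)


class _DependencyTracker:
    """Finalization rounds of (column, row group) tasks, for legality checks."""

    def __init__(self) -> None:
        self.done: Dict[Tuple[int, int], int] = {}  # (column, group) -> round

    def mark(self, j: int, g: int, d: int) -> None:
        self.done[(j, g)] = d

    def assert_ready(self, j: int, g: int, d: int, reader_j: int) -> None:
        got = self.done.get((j, g))
        if got is None:
            raise RuntimeError(
                f"scheduler bug: column {reader_j} round {d} reads "
                f"unfinalized task (column {j}, group {g})"
            )
        if not (got < d or (got == d and j < reader_j)):
            raise RuntimeError(
                f"scheduler bug: column {reader_j} round {d} reads task "
                f"(column {j}, group {g}) finalized in round {got}"
            )


def solve_parallel_sim(
    seq: RnaSequence,
    scheme: Optional[ScoringScheme] = None,
    epsilon: float = 0.4,
    q: Optional[int] = None,
    min_loop: int = 0,
    max_q: int = 8,
    sparsified: bool = False,
    keep_dp: bool = True,
) -> SolveResult:
    """Simulate the round-synchronous per-column folding algorithm.

    ``params["schedule"]`` of the result holds the :class:`RoundSchedule`
    (per-column operation counts, per-column OCT counts Z_j, and the executed
    round structure).  The final L matrix is identical to the serial engines'.
    """
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
    sig_oct: Dict[Tuple[int, int], int] = {}
    sig_step: Dict[Tuple[int, int], int] = {}
    sched = RoundSchedule(q=q)
    deps = _DependencyTracker()

    ix = base_indices(seq).tolist()
    bt = scheme.beta_table().tolist()

    def provider(gp: int, g: int) -> List[List[int]]:
        rlo, clo = q * gp, q * g
        return [L[r][clo : clo + q] for r in range(rlo, rlo + q)]

    def run_task(j: int, g: int, d: int, ops: OpCounters) -> None:
        gj = j // q
        lo = q * g
        tstart = q * gj
        bj = bt[ix[j - 1]]
        split = 0

        # --- declared reads, checked against the schedule (Invariant: only
        # earlier rounds, or the same round strictly to the left) ---
        for gfull in range(g + 1, gj):
            deps.assert_ready(j, gfull, d, j)  # the subvector L[K_gfull, j]
            for c in range(q * gfull, q * gfull + q):  # block L[I_g, K_gfull]
                deps.assert_ready(c, g, d, j)
        if g < gj and tstart < j:  # tail cells L[k, j], k in [q*gj, j)
            deps.assert_ready(j, gj, d, j)
        for c in range(max(lo + 1, 2), min(lo + q, j)):  # own-group splits L[i, c]
            deps.assert_ready(c, g, d, j)
        if g < gj:  # tail split values L[i, k], row i in I_g, k in [q*gj, j)
            for c in range(max(tstart, 2), j):
                deps.assert_ready(c, g, d, j)
        i_top = min(lo + q - 1, j - 2)
        hi_nb = min(i_top, j - 4)  # rows whose co-terminus read (i+1, j-1) is non-base
        if hi_nb >= lo:
            for h in {(lo + 1) // q, (hi_nb + 1) // q}:
                deps.assert_ready(j - 1, h, d, j)

        # --- pull full-Kgroup contributions through the shared tables ---
        acc: Optional[DeltaVector] = None
        for gfull in range(g + 1, gj):
            if sparsified:
                # gating signature: strict OCT bits plus the vacuous
                # co-terminus bit when the group ends exactly at j
                m = sig_oct.get((gfull, j), 0)
                if q * gfull + q == j:
                    m |= 1 << (q - 1)
                if not (m and sig_dot(sig_step.get((g, gfull), 0), m)):
                    continue
            flo = q * gfull
            x0 = L[flo][j]
            delta = 0
            prev = x0
            for r in range(flo + 1, flo + q):
                cur = L[r][j]
                delta = delta * D + (prev - cur)
                prev = cur
            y = mul.access(g, gfull, delta, q, D, provider, ops)
            contrib = y + x0
            acc = contrib if acc is None else delta_max(acc, contrib, maxt, ops)
        if acc is not None:
            vals = acc.decode()
            for t in range(q):
                Lp[lo + t][j] = vals[t]

        # --- finish the subvector's cells ---
        for i in range(i_top, lo - 1, -1):
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
                for k in range(tstart, j):
                    cand = Li[k] + L[k][j]
                    split += 1
                    if cand > best:
                        best = cand
                if i + 1 == pend and pend < tstart:
                    cand = L[i + 1][j]
                    split += 1
                    if cand > best:
                        best = cand
            Lp[i][j] = best
            lc = L[i + 1][j - 1] + bj[ix[i]] if (j - 1 - i) > min_loop else NEG_INF
            Lc[i][j] = lc
            lij = best if best >= lc else lc
            L[i][j] = lij
            if lij == lc and lc > best:
                octf[i][j] = True
            if lij > L[i + 1][j]:
                stepf[i][j] = True
                key = (i // q, gj)
                sig_step[key] = sig_step.get(key, 0) | (1 << (j - tstart))
        if lo + q <= j:
            m = 0
            for x in range(q):
                if octf[lo + x][j]:
                    m |= 1 << x
            sig_oct[(g, j)] = m
        ops.split_comparisons += split

    max_round = n // q if n >= 1 else -1
    for d in range(max_round + 1):
        this_round: List[Tuple[int, int]] = []
        for j in range(1, n + 1):
            g = j // q - d
            if g < 0:
                continue
            ops = OpCounters()
            run_task(j, g, d, ops)
            deps.mark(j, g, d)
            this_round.append((j, g))
            sched.ops_by_column[j] = sched.ops_by_column.get(j, 0) + ops.total()
            sched.rounds_by_column[j] = sched.rounds_by_column.get(j, 0) + 1
            counters += ops
        if this_round:
            sched.rounds.append(this_round)
    for j in range(1, n + 1):
        sched.oct_by_column[j] = sum(1 for i in range(j) if octf[i][j])

    assert int(L[0][n]) != NEG_INF, "matrix left unfinished"
    assert sum(sched.ops_by_column.values()) == counters.total()
    return SolveResult(
        score=int(L[0][n]),
        engine="parallel-sim",
        counters=counters,
        dp=to_state(L, Lp, Lc, grid, octf, stepf) if keep_dp else None,
        params={
            "q": q,
            "epsilon": epsilon,
            "min_loop": min_loop,
            "sparsified": sparsified,
            "schedule": sched,
        },
    )
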