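"""Random-sequence generation and the operation-count benchmark harness.

The benchmark protocol: a fixed number of randomly
generated sequences per size (20 by default), every engine run on the same
sequences, and costs reported not in seconds but in counted operations --
split-point comparisons plus lookup-table events -- to abstract from
compiler and interpreter effects.  Base composition is i.i.d. uniform over
{A,U,C,G} (an assumption, recorded in the report header).  The naive engine's count is
sequence-independent and equals C(n+1, 3) per sequence, so the cubic column
is reproducible exactly from the closed form; the other engines'
totals depend on the drawn sequences and on this package's fixed counting
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import OpCounters, RnaSequence, ScoringScheme, SolveResult
from .fourrussians import solve_fr
from .naive import solve_naive
from .parallel import solve_parallel_sim
from .sparse import solve_sparse
from .sparse_fr import solve_sfr

_BASES = np.array(list("ACGU"))

ENGINES: Dict[str, Callable[..., SolveResult]] = {
    "naive": solve_naive,
    "sp": solve_sparse,
    "fr": solve_fr,
    "sfr": solve_sfr,
    "parallel-sim": solve_parallel_sim,
}

_COUNTER_COLS = [
    "split_comparisons",
    "mul_builds",
    "mul_lookups",
    "max_builds",
    "max_lookups",
    "g_builds",
]


def random_sequence(n: int, seed: int) -> RnaSequence:
    """I.i.d. uniform random RNA sequence; identical (n, seed) gives an
    identical sequence."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return RnaSequence("")
    rng = np.random.default_rng(seed)
    return RnaSequence("".join(rng.choice(_BASES, size=n)))


def replicate_seed(seed: int, n: int, rep: int) -> int:
    """Deterministic per-replicate seed below 2**31, platform independent."""
    return int(np.random.SeedSequence([seed, n, rep]).generate_state(1)[0] % (2**31))


@dataclass
class BenchmarkReport:
    """Per-run rows and per-(size, engine) aggregates of counted operations."""

    sizes: List[int]
    reps: int
    seed: int
    engines: List[str]
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def totals(self) -> pd.DataFrame:
        """Sum of counted operations over replicates, per (n, engine)."""
        agg = self.rows.groupby(["n", "engine"], sort=True)["total_ops"].sum()
        return agg.unstack("engine")

    @property
    def per_sequence(self) -> pd.DataFrame:
        """Mean counted operations per sequence, per (n, engine)."""
        agg = self.rows.groupby(["n", "engine"], sort=True)["total_ops"].mean()
        return agg.unstack("engine")

    def to_tsv(self, path: Union[str, Path]) -> None:
        header = (
            f"# rnassf benchmark: sizes={','.join(map(str, self.sizes))} "
            f"reps={self.reps} seed={self.seed} "
            f"engines={','.join(self.engines)}\n"
            "# sequences: i.i.d. uniform over {A,U,C,G}\n"
            "# total_ops = split comparisons + table builds + gated MUL lookups\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.rows.to_csv(fh, sep="\t", index=False)


def run_benchmark(
    sizes: Sequence[int],
    reps: int = 20,
    seed: int = 1,
    engines: Optional[Sequence[str]] = None,
    scheme: Optional[ScoringScheme] = None,
    epsilon: float = 0.4,
) -> BenchmarkReport:
    """Run every requested engine on the same seeded random sequences.

    All engines must agree on the optimal score of every sequence; a
    disagreement is an engine bug and raises immediately.
    """
    engines = list(engines) if engines is not None else list(ENGINES)
    unknown = set(engines) - set(ENGINES)
    if unknown:
        raise ValueError(f"unknown engines: {sorted(unknown)}")
    records: List[dict] = []
    for n in sizes:
        for rep in range(reps):
            rseed = replicate_seed(seed, n, rep)
            seq = random_sequence(n, rseed)
            scores: Dict[str, int] = {}
            for name in engines:
                res = ENGINES[name](seq, scheme=scheme, keep_dp=False, **(
                    {} if name in ("naive", "sp") else {"epsilon": epsilon}
                ))
                scores[name] = res.score
                c: OpCounters = res.counters
                rec = {
                    "n": n,
                    "rep": rep,
                    "seed": rseed,
                    "engine": name,
                    "score": res.score,
                    "total_ops": c.total(),
                }
                rec.update({col: getattr(c, col) for col in _COUNTER_COLS})
                records.append(rec)
            if len(set(scores.values())) > 1:
                raise RuntimeError(
                    f"engines disagree on n={n} rep={rep} (seed {rseed}): {scores}"
                )
    rows = pd.DataFrame.from_records(records)
    return BenchmarkReport(
        sizes=list(sizes), reps=reps, seed=seed, engines=engines, rows=rows
    )
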