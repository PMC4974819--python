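"""One-call front door: fold a sequence with any engine, with traceback."""

from __future__ import annotations

from typing import Optional, Union

from .bench import ENGINES
from .core import RnaSequence, ScoringScheme, SolveResult, normalize_sequence
from .traceback import traceback


def fold(
    seq: Union[str, RnaSequence],
    engine: str = "naive",
    scheme: Optional[ScoringScheme] = None,
    epsilon: float = 0.4,
    q: Optional[int] = None,
    min_loop: int = 0,
    with_traceback: bool = True,
) -> SolveResult:
    """Fold one sequence and (optionally) recover an optimal structure.

    ``engine`` is one of naive, sp, fr, sfr, parallel-sim.  Raw strings are
    normalized (uppercased, T mapped to U) first.
    """
    if isinstance(seq, str):
        seq = normalize_sequence(seq)
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; choose from {sorted(ENGINES)}")
    kwargs = {"scheme": scheme, "min_loop": min_loop, "keep_dp": True}
    if engine not in ("naive", "sp"):
        kwargs.update(epsilon=epsilon, q=q)
    res = ENGINES[engine](seq, **kwargs)
    if with_traceback:
        res.folding = traceback(res.dp, seq, scheme, min_loop=min_loop)
    return res
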