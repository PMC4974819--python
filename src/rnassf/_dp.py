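"""Internal helpers shared by the per-cell (list-based) engines."""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .core import NEG_INF, BlockGrid, DpState

Matrix = List[List[int]]


def init_lists(n: int) -> tuple[Matrix, Matrix, Matrix]:
    """Sentinel-filled (n+1)x(n+1) list matrices with L base cases set.

    Plain nested lists: the block engines touch cells one at a time, where
    Python list indexing beats ndarray scalar access by a wide margin.
    """
    L = [[NEG_INF] * (n + 1) for _ in range(n + 1)]
    Lp = [[NEG_INF] * (n + 1) for _ in range(n + 1)]
    Lc = [[NEG_INF] * (n + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        L[i][i] = 0
        if i < n:
            L[i][i + 1] = 0
    return L, Lp, Lc


def to_state(
    L: Matrix,
    Lp: Matrix,
    Lc: Matrix,
    grid: BlockGrid,
    octf: Optional[List[List[bool]]] = None,
    stepf: Optional[List[List[bool]]] = None,
) -> DpState:
    return DpState(
        L=np.array(L, dtype=np.int64),
        Lp=np.array(Lp, dtype=np.int64),
        Lc=np.array(Lc, dtype=np.int64),
        grid=grid,
        oct=None if octf is None else np.array(octf, dtype=bool),
        step=None if stepf is None else np.array(stepf, dtype=bool),
    )
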