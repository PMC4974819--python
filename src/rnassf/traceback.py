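"""Recover one optimal folding from a solved DP state.

Works from the L matrix alone (plus the scoring scheme), so it applies
uniformly to every engine: the sparsifying engines may leave Lp slightly
below its unrestricted value inside strictly-OCT cells, but their L matrices
are exact.  Deterministic tie-break: prefer the co-terminus case (pair i with
j-1) when it both attains the optimum and contributes a positive score;
otherwise take the smallest split point k with L[i,k] + L[k,j] = L[i,j].
Zero-scoring pairs are never emitted, so an empty folding is returned for
pair-free sequences.
"""

from __future__ import annotations

from typing import List, Optional, Set, Tuple

from .core import DpState, Folding, RnaSequence, ScoringScheme


def traceback(
    dp: DpState,
    seq: RnaSequence,
    scheme: Optional[ScoringScheme] = None,
    min_loop: int = 0,
) -> Folding:
    scheme = scheme or ScoringScheme.default()
    n = seq.n
    if dp.n != n:
        raise ValueError(f"DP state is for n={dp.n}, sequence has n={n}")
    L = dp.L
    res = seq.residues
    pairs: Set[Tuple[int, int]] = set()
    stack: List[Tuple[int, int]] = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        lij = int(L[i, j])
        b = scheme.beta(res[i], res[j - 1])
        if b > 0 and (j - 1 - i) > min_loop and int(L[i + 1, j - 1]) + b == lij:
            pairs.add((i, j - 1))
            stack.append((i + 1, j - 1))
            continue
        for k in range(i + 1, j):
            if int(L[i, k]) + int(L[k, j]) == lij:
                stack.append((i, k))
                stack.append((k, j))
                break
        else:
            raise RuntimeError(
                f"inconsistent DP state at cell ({i},{j}): no co-terminus or "
                "split decomposition attains L[i,j] -- engine bug"
            )
    folding = Folding.of(pairs)
    folding.validate(n)
    got = folding.score(seq, scheme)
    if got != int(L[0, n]):
        raise RuntimeError(
            f"traceback score {got} != L[0,n] = {int(L[0, n])} -- engine bug"
        )
    return folding
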