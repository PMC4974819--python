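"""Shared domain types for single-sequence RNA folding (SSF).

The SSF problem: given an RNA string ``s`` of length ``n`` over {A,U,C,G},
find a *folding* -- a set of non-crossing base pairs, each position used at
most once -- maximizing the sum of pair scores ``beta``.  Under the default
scheme (score 1 for Watson-Crick pairs AU/UA/CG/GC, 0 otherwise) this is
base-pair maximization.

Conventions used throughout the package:

* 0-based positions; the substring ``s[i:j]`` is half-open, i.e. it does not
  contain position ``j``.
* Score matrices are ``(n+1) x (n+1)``; the answer lives at ``L[0, n]``.
* Cells with ``j < i`` (and partitioned/co-terminus scores that are
  undefined, e.g. ``Lp`` when no split point exists) hold the sentinel
  :data:`NEG_INF`, never read as a score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Optional, Tuple

import numpy as np

#: Sentinel standing in for "minus infinity" in integer score matrices.  Large
#: enough in magnitude that no sum of valid scores can reach it, small enough
#: that adding two sentinels does not overflow int64.
NEG_INF: int = -(2**40)

_VALID_BASES = frozenset("ACGU")


def normalize_sequence(raw: str) -> "RnaSequence":
    """Normalize raw text into a validated :class:`RnaSequence`.

    Uppercases, strips all whitespace, and maps DNA-style T to U.  Any other
    character raises ``ValueError`` naming the offending (post-normalization)
    position.  Ambiguity codes (N, R, ...) are rejected rather than scored
    zero, so that the discreteness guarantees of the scoring scheme hold.
    """
    cleaned = "".join(raw.split()).upper().replace("T", "U")
    if not cleaned:
        raise ValueError("empty sequence after whitespace stripping")
    for pos, ch in enumerate(cleaned):
        if ch not in _VALID_BASES:
            raise ValueError(
                f"invalid residue {ch!r} at position {pos}: expected A, C, G, U (or T)"
            )
    return RnaSequence(cleaned)


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA string over {A,U,C,G}."""

    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - _VALID_BASES
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)}; use normalize_sequence()")

    @property
    def n(self) -> int:
        return len(self.residues)

    def s(self, i: int, j: int) -> str:
        """Half-open substring ``s_{i,j}`` = residues i..j-1 (excludes j)."""
        if not (0 <= i <= j <= self.n):
            raise IndexError(f"substring bounds ({i},{j}) outside [0,{self.n}]")
        return self.residues[i:j]

    def __len__(self) -> int:
        return self.n

    def __str__(self) -> str:
        return self.residues


_DEFAULT_PAIRS = {("A", "U"): 1, ("U", "A"): 1, ("C", "G"): 1, ("G", "C"): 1}


@dataclass(frozen=True)
class ScoringScheme:
    """Integer pair-scoring function beta.

    ``pair_score`` maps ordered nucleotide pairs to non-negative integers
    (both orientations always present).  ``beta_max`` is the largest score and
    ``D = beta_max + 1`` the size of the difference alphabet: because adding
    one nucleotide to a subsequence changes the optimum by at most the best
    single pair, vertical neighbors in any score-matrix column differ by a
    value in ``[0, beta_max]``.  That discreteness is what the Four-Russians
    encodings rely on, and it requires integer scores.
    """

    pair_score: Dict[Tuple[str, str], int] = field(
        default_factory=lambda: dict(_DEFAULT_PAIRS)
    )

    def __post_init__(self) -> None:
        sym: Dict[Tuple[str, str], int] = {}
        for (a, b), v in self.pair_score.items():
            if a not in _VALID_BASES or b not in _VALID_BASES:
                raise ValueError(f"pair {(a, b)} contains a non-RNA residue")
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise ValueError(f"score for {(a, b)} must be a non-negative integer")
            if sym.setdefault((a, b), v) != v or sym.setdefault((b, a), v) != v:
                raise ValueError(f"conflicting scores for unordered pair {(a, b)}")
        object.__setattr__(self, "pair_score", sym)

    @property
    def beta_max(self) -> int:
        return max(self.pair_score.values(), default=0)

    @property
    def D(self) -> int:
        """Difference-alphabet size used by the Delta-encodings (at least 2)."""
        return max(2, self.beta_max + 1)

    def beta(self, a: str, b: str) -> int:
        """Symmetric pair score; zero for any pair not configured."""
        if a not in _VALID_BASES or b not in _VALID_BASES:
            raise ValueError(f"beta() arguments must be RNA residues, got {(a, b)}")
        return self.pair_score.get((a, b), 0)

    def beta_table(self) -> np.ndarray:
        """4x4 score matrix indexed by :func:`base_indices` order (A,C,G,U)."""
        t = np.zeros((4, 4), dtype=np.int64)
        for (a, b), v in self.pair_score.items():
            t[_BASE_ORDER[a], _BASE_ORDER[b]] = v
        return t

    @classmethod
    def default(cls) -> "ScoringScheme":
        return cls()

    @classmethod
    def from_pairs(cls, pairs: Dict[str, int]) -> "ScoringScheme":
        """Build from a JSON-style map of two-letter pair strings, e.g.
        ``{"GC": 1, "AU": 1}``; both orientations are implied."""
        ps: Dict[Tuple[str, str], int] = {}
        for key, v in pairs.items():
            if len(key) != 2:
                raise ValueError(f"pair key {key!r} must be two residues")
            a, b = key[0].upper(), key[1].upper()
            ps[(a, b)] = v
            ps[(b, a)] = v
        return cls(ps)


_BASE_ORDER = {"A": 0, "C": 1, "G": 2, "U": 3}


def base_indices(seq: RnaSequence) -> np.ndarray:
    """Sequence as small integers (A=0, C=1, G=2, U=3) for fast beta lookup."""
    return np.array([_BASE_ORDER[c] for c in seq.residues], dtype=np.int64)


def beta(scheme: ScoringScheme, a: str, b: str) -> int:
    """Functional alias for :meth:`ScoringScheme.beta`."""
    return scheme.beta(a, b)


def choose_q(n: int, epsilon: float, D: int = 2, max_q: int = 8) -> int:
    """Block size q = max(1, floor(epsilon * log_D n)), capped at ``max_q``.

    The Four-Russians analysis takes q = eps*log_D(n) with eps in (0, 0.5) so
    that the on-demand lookup tables stay sub-quadratic; eps = 0.5 exactly is
    accepted since it is harmless at any finite n.  The cap bounds table
    memory (D^(q-1) MUL entries per block).
    """
    if not (0.0 < epsilon <= 0.5):
        raise ValueError(f"epsilon must lie in (0, 0.5], got {epsilon}")
    if n < 1:
        raise ValueError("choose_q requires n >= 1")
    if D < 2:
        raise ValueError("difference alphabet size D must be >= 2")
    q = int(epsilon * math.log(n, D)) if n > 1 else 1
    return max(1, min(q, max_q))


@dataclass(frozen=True)
class BlockGrid:
    """Tiling of matrix indices 0..n into Kgroups of size q.

    Group g covers indices {q*g, ..., q*g+q-1} clipped to [0, n]; row groups
    I_g are the same intervals.  A group is *full* (relative to an exclusive
    upper limit) when all q of its members fall below that limit.
    """

    n: int
    q: int

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ValueError("block size q must be >= 1")
        if self.n < 0:
            raise ValueError("n must be >= 0")

    def group_of(self, i: int) -> int:
        return i // self.q

    @property
    def n_groups(self) -> int:
        """Number of groups needed to cover indices 0..n inclusive."""
        return self.n // self.q + 1

    def members(self, g: int) -> range:
        """Members of Kgroup g clipped to [0, n]."""
        lo = self.q * g
        return range(lo, min(lo + self.q, self.n + 1))

    def is_full(self, g: int, limit: Optional[int] = None) -> bool:
        """True iff group g has exactly q members below ``limit`` (default n+1)."""
        hi = self.n + 1 if limit is None else limit
        return self.q * g + self.q <= hi


@dataclass(frozen=True)
class Folding:
    """A set of non-crossing base pairs (k, l), 0 <= k < l < n."""

    pairs: FrozenSet[Tuple[int, int]]

    @classmethod
    def of(cls, pairs: Iterable[Tuple[int, int]]) -> "Folding":
        return cls(frozenset((int(k), int(l)) for k, l in pairs))

    def validate(self, n: int) -> None:
        """Raise ``ValueError`` unless pairs are in-range, disjoint and
        non-crossing.  O(|pairs| log |pairs|) via a sweep with a stack."""
        seen: set = set()
        for k, l in self.pairs:
            if not (0 <= k < l < n):
                raise ValueError(f"pair ({k},{l}) out of range for n={n}")
            for p in (k, l):
                if p in seen:
                    raise ValueError(f"position {p} participates in more than one pair")
                seen.add(p)
        stack: list = []  # close positions of currently open pairs
        for k, l in sorted(self.pairs):
            while stack and stack[-1] < k:
                stack.pop()
            if stack and l > stack[-1]:
                raise ValueError(f"pair ({k},{l}) crosses a pair closing at {stack[-1]}")
            stack.append(l)

    def score(self, seq: RnaSequence, scheme: ScoringScheme) -> int:
        return sum(scheme.beta(seq.residues[k], seq.residues[l]) for k, l in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class DpState:
    """The three DP matrices plus sparsity annotations.

    ``L[i, j]`` is the optimal score of the half-open subsequence s_{i,j};
    ``Lp`` the best *partitioned* (split at some k in (i,j)) score and ``Lc``
    the best *co-terminus* (positions i and j-1 paired) score, so that
    ``L = max(Lp, Lc)`` for j > i+1 and ``L[i,i] = L[i,i+1] = 0``.

    ``oct``/``step`` are per-cell flags (filled by the sparsifying engines,
    None otherwise): a cell is OCT when every optimal folding is co-terminus
    (L = Lc > Lp) and STEP when L[i,j] > L[i+1,j], i.e. position i is paired
    in every optimal folding.
    """

    L: np.ndarray
    Lp: np.ndarray
    Lc: np.ndarray
    grid: BlockGrid
    oct: Optional[np.ndarray] = None
    step: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.L.shape[0] - 1


@dataclass
class OpCounters:
    """Named work counters -- the unit of the comparison-count benchmark.

    ``split_comparisons`` counts candidate split points evaluated cell-by-cell
    (one unit per candidate k examined while computing some Lp[i,j]); the
    remaining counters record on-demand lookup-table events.  A ``*_lookups``
    event is a table access answered from cache; a ``*_builds`` event creates
    one new entry.  Scalar bookkeeping that touches no table (for example the
    large-offset shortcut of the encoded vector max) is not an event.
    """

    split_comparisons: int = 0
    mul_lookups: int = 0
    mul_builds: int = 0
    max_lookups: int = 0
    max_builds: int = 0
    g_builds: int = 0

    def total(self) -> int:
        """Total counted operations: split comparisons + table builds +
        (gated) MUL lookups.

        The counted unit is a candidate-producing evaluation or a
        table-entry creation.  Merging candidates into a running maximum is
        never counted, in any engine: the baseline does not count its
        per-cell ``max`` updates, and correspondingly a MAX-table cache hit
        (the encoded form of the same merge) is reported in ``max_lookups``
        but is not an operation.  MAX-table *builds* do create entries and
        count.
        """
        return (
            self.split_comparisons
            + self.mul_lookups
            + self.mul_builds
            + self.max_builds
            + self.g_builds
        )

    def __iadd__(self, other: "OpCounters") -> "OpCounters":
        self.split_comparisons += other.split_comparisons
        self.mul_lookups += other.mul_lookups
        self.mul_builds += other.mul_builds
        self.max_lookups += other.max_lookups
        self.max_builds += other.max_builds
        self.g_builds += other.g_builds
        return self


@dataclass
class SolveResult:
    """What every engine returns."""

    score: int
    engine: str
    counters: OpCounters
    dp: Optional[DpState] = None
    folding: Optional[Folding] = None
    params: Dict[str, object] = field(default_factory=dict)
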