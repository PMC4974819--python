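# rnassf — single-sequence RNA folding with interchangeable DP engines

`rnassf` computes the maximum-score non-crossing secondary structure of one
RNA sequence (the classic single-sequence folding / base-pair maximization
problem) with five interchangeable dynamic-programming engines, and counts
exactly how much work each one does.  It is aimed at people studying
*algorithmic* speedups of folding-type dynamic programs — sparsification,
Four-Russians tabling, and their combination — rather than at thermodynamic
structure prediction: the scoring is an arbitrary non-negative integer pair
score β, with the Watson–Crick counting scheme (AU/UA/CG/GC = 1) as the
default.

## The problem and the recurrence

For a sequence *s* of length *n* over {A,U,C,G}, a folding is a set of
non-crossing pairs (k, l), each position in at most one pair, scored by
Σ β(s_k, s_l).  Writing s_{i,j} for the half-open substring s_i…s_{j−1},
the optimum L[i,j] of s_{i,j} satisfies, for j > i+1:

    L[i,j]  = max(Lᵖ[i,j], Lᶜ[i,j])
    Lᵖ[i,j] = max_{i<k<j} ( L[i,k] + L[k,j] )        — partitioned at k
    Lᶜ[i,j] = L[i+1,j−1] + β(s_i, s_{j−1})           — ends paired

with L[i,i] = L[i,i+1] = 0 and the answer at L[0,n].  Evaluating Lᵖ is the
Θ(n³) bottleneck; the engines differ only in how many split-point candidates
they actually touch:

| engine | idea |
|---|---|
| `naive` | all split points; exactly C(n+1,3) candidate evaluations |
| `sp` | sparsification: only the mandatory k=i+1 plus k with (i,k) STEP and (k,j) OCT |
| `fr` | on-demand Four-Russians: q×q blocks, Δ-encoded subcolumns, memoized max-plus (MUL) and vector-max (MAX) tables |
| `sfr` | both: q-bit STEP/OCT signatures gate every MUL access (via the on-demand G table) |
| `parallel-sim` | round-synchronous simulation of one process per column (n²/log²n-style wavefront), optionally signature-gated |

All five provably produce the identical L matrix; the package verifies this
cell-for-cell in its test suite, and every engine returns an `OpCounters`
with its split comparisons and table events.  A shared traceback recovers an
optimal structure from any engine's matrices.

## Worked example

```python
from rnassf import fold, dotbracket, normalize_sequence

seq = normalize_sequence("GGGCUAUUAGCUCAGUUGGUUAGAGC")
res = fold(seq, engine="sfr")
print(res.score)                      # 9
print(dotbracket(seq, res.folding))   # (..((().(())((.)(....)))))
```

The score 9 is the maximum number of Watson–Crick pairs over all
non-crossing structures of this 26-mer (adjacent positions may pair under
the default zero minimum-loop convention), and the dot-bracket line is one
optimal structure.  Comparing engines on a random 128-mer
(`python examples/compare_engines.py`):

```
engine         score    split   mulB   mulL  maxB   gB    total
naive             56   349504      0      0     0    0   349504
sp                56    16501      0      0     0    0    16501
fr                56    12097   3649  81695     8    0    97449
sfr               56     9834   2789   2721     8  118    15470
```

Identical scores are the correctness check; `total` (split comparisons +
table builds + gated MUL lookups) shows the combined engine beating both of
its parents — here 15,470 vs 16,501 (sp) and 97,449 (fr) against the
baseline's 349,504.  The `examples/` directory has one short script per
capability (single-sequence folding, engine comparison, the benchmark,
the parallel schedule, custom scoring schemes), and the same functionality
is exposed as a CLI:

```
rnassf fold --fasta input.fa --engine sfr --dotbracket out.db
rnassf bench --sizes 64,128 --reps 20 --seed 1 --engines naive,sp,fr,sfr --out report.tsv
```

## What it is not

No thermodynamic nearest-neighbor energies, no partition function, no
pseudoknots, and no true multithreading — the parallel engine is a
deterministic simulation whose contract is the dependency structure and
per-process operation accounting.  See `docs/methods.md` for the model,
parameter, and convention details.
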