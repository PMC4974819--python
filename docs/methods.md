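# Methods

## Model and conventions

The package solves single-sequence RNA folding in its combinatorial form:
maximize Σ β(s_k, s_l) over sets of non-crossing position pairs, each
position used at most once.  β is any symmetric map from nucleotide pairs to
non-negative integers; the default is the base-pair-maximization scheme
(AU/UA/CG/GC = 1, all else 0).  Integrality matters: the engines' encoding
machinery relies on score differences living in a finite alphabet, so
fractional energies are out of scope, as are nearest-neighbor stacking
models, pseudoknots, and the partition function.

Coordinates are 0-based and substrings half-open: s_{i,j} = s_i…s_{j−1}.
The three matrices L, Lᵖ (best partitioned score) and Lᶜ (best co-terminus
score, ends paired) are (n+1)×(n+1); L[i,i] = L[i,i+1] = 0, the answer is
L[0,n], and cells below the diagonal — or Lᵖ/Lᶜ values that do not exist,
such as Lᵖ of a two-letter substring — hold an integer sentinel (−2⁴⁰) that
is never interpreted as a score.  By default adjacent positions may pair
(zero minimum loop); an optional `min_loop` parameter suppresses pairs
(i, j−1) spanning ≤ min_loop unpaired positions by making the co-terminus
case unavailable.  Ambiguity codes are rejected outright rather than scored
zero, because a silent zero would break the discreteness guarantees below.

Two structural facts carry all the speedups.  *Monotonicity/discreteness*:
dropping the first position of a substring can only lower the optimum, and
by at most one pair, so consecutive entries of any L column differ by a
value in [0, β_max]; columns are D-discrete with D = β_max + 1.
*Candidate sufficiency*: every cell has an optimal split point k that is
either the mandatory k = i+1, or satisfies "(i,k) is STEP and (k,j) is
OCT", where STEP means L[i,k] > L[i+1,k] (position i pairs in every optimal
folding) and OCT means every optimal folding of s_{k,j} is co-terminus.

One consequence of the OCT definition is easy to miss and was caught here
by the brute-force oracle during development: a single-nucleotide
sub-instance s_{j−1,j} admits no split point at all, so its only folding is
*vacuously* co-terminus and k = j−1 is a legitimate candidate for every
row, even though the matrix-level strict test L = Lᶜ > Lᵖ can never flag a
base cell.  The sparsifying engines therefore always treat k = j−1 as an
OCT-like candidate (and fold its bit into the gating signatures), while the
reported OCT flags, Z totals and `classify_cell` keep the strict
definition, under which base cells are neither OCT nor STEP.

## The engines

**naive** sweeps columns j = 1…n, rows top-down; as each L[k,j] is
finalized it is pushed as split point k into Lᵖ[i,j] for all i < k.  Each
push is one counted split comparison, giving exactly C(n+1,3) per sequence
— the quantity the cubic column of the benchmark reports.

**sp** (sparsification) keeps, per finished column k, the list of its STEP
rows; when a cell (k,j) of the current column classifies as OCT (or is the
base cell k = j−1) it pushes candidate k into exactly the STEP rows of
column k.  The mandatory k = i+1 is evaluated at each cell.  List upkeep is
O(1) amortized per cell.  With pruning disabled (`debug_full=True`) every
split point is pushed; that this never changes a single L value is the
soundness check for the candidate sets.  Because a sparsified Lᵖ may sit
below its unrestricted value inside strictly-OCT cells (where L = Lᶜ
regardless), cross-engine equality is asserted on L, and OCT flag sets of
restricted engines are supersets of the unrestricted ones — the safe
direction for pruning.

**fr** (on-demand Four-Russians) tiles the matrix into q×q blocks and
q-subcolumns.  A D-discrete length-q vector is Δ-encoded as (first element,
base-D integer of its q−1 consecutive differences, first difference most
significant); adding a constant moves only the first element.  Two memo
tables, both built lazily and only for keys actually demanded, replace bulk
work: MUL[(g′,g,Δ)] caches the row-wise max-plus product of finalized block
L[I_g′,K_g] with (0,Δ) (≤ D^(q−1) entries per block, O(q²) to build); MAX
caches offset element-wise maxima of two encoded vectors (O(q) to build).
When the offset between two vectors exceeds (q−1)(D−1) the higher one
dominates outright and no table is touched — note this threshold is the
D-discrete generalization; the familiar q−1 rule is its D = 2 case, and
using q−1 for D > 2 would be wrong (a steeply falling vector can dip under
a flat one).  Per column, each full subcolumn is encoded once and combined
into one running accumulator per lower row group, decoded back into Lᵖ
exactly once, just before that row group's cells finish.  Split points in
partial groups (the group containing j, the cell's own group, and the
always-evaluated mandatory k = i+1) are handled cell-by-cell.

**sfr** adds signature gating: sigOct(g,j) marks which rows of subcolumn
L[K_g,j] are OCT (plus the vacuous bit when the group ends at j), and
sigStep(g′,g) marks which columns of block (g′,g) contain a STEP row.  A
MUL access for (g′,g) happens only if the bitwise dot product of the two
signatures is 1 — by the candidate-sufficiency argument lifted to blocks,
a zero dot product proves the block cannot contribute an optimal split for
any of its rows.  The on-demand G table maps (g, signature) to the row
groups passing the test so each subcolumn iterates only over them; cached
entries are re-verified against the live signatures on every hit.
Cell-by-cell work in partial groups uses the sparsified candidate
iteration.  Disabling the gate must change counters only, never values;
this is tested.

**parallel-sim** executes the same block computation as one logical process
per column in synchronous rounds: in round d, column j computes subvector
L[I_{g_j−d}, j], so column j finishes after ⌈(j+1)/q⌉ rounds and the whole
matrix after n/q + 1.  Rounds run serially, columns left-to-right within a
round; this is a *simulation* whose contract is the dependency structure
and per-column operation accounting, not threads.  Every read is declared
and checked: sources must be finalized in an earlier round, or — for the
streaming reads along the current antidiagonal, including the co-terminus
cell in column j−1 — in the same round by a strictly smaller column.  (A
strict "earlier rounds only" rule is impossible: the co-terminus dependency
always connects neighboring columns inside a round.)  MUL/MAX tables are
shared; a build is charged to the first, i.e. lowest-index, column that
demands the entry.  The sparsified variant gates only the MUL accesses.
Reported quantities are per-column operation totals, their maximum (the
makespan), per-column OCT counts Z_j, and the executed round structure.

## Counting convention

The benchmark reports work in counted operations, not seconds, to stay
compiler- and interpreter-independent.  The counted unit is a
*candidate-producing evaluation or a table-entry creation*:

* one unit per split-point candidate evaluated cell-by-cell;
* one unit per MUL access (build or cache hit — the access stands in for
  the q split-point evaluations it replaces);
* one unit per created table entry (MUL, MAX, or G build).

Merging candidates into a running maximum is never counted, in any engine:
the baseline does not count its per-cell `max` updates or the final
two-way max of the recurrence, and the encoded analogue of that merge — a
MAX-table cache hit, or the large-offset shortcut that touches no table —
is likewise bookkeeping (hits are still reported in `max_lookups` for
transparency; they are not in `total()`).  Under this convention the naive
engine's total is exactly C(n+1,3), and the combined engine's total was at
most min(sp, fr) on every one of 400 random instances examined at
n ∈ {64, 128}.  Operation counts reported by other implementations of these methods are
not comparable cell-for-cell, since counting conventions differ; engine
orderings and the closed-form baseline count are the portable quantities.

## Parameters

| parameter | default | meaning |
|---|---|---|
| β table | WC pairs = 1 | any non-negative integer pair scores; D = β_max+1 |
| ε | 0.4 | block size q = max(1, ⌊ε·log_D n⌋); ε ∈ (0, 0.5] |
| max_q | 8 | cap on q, bounding MUL memory at D^(q−1) entries/block |
| q | derived | explicit override, used to exercise D > 2 at modest n (ε·log_D n rounds to 1 there) |
| min_loop | 0 | minimum unpaired span inside a pair |
| reps | 20 | benchmark sequences per size |

At the benchmark sizes the derived block sizes are q = 2 (n = 64, 128) and
q = 3 (n = 256).

## Synthetic data

All inputs are generated: i.i.d. uniform sequences over {A,U,C,G} from a
seeded generator (`random_sequence`), 20 per size, with per-replicate seeds
derived deterministically from one master seed, kept below 2³¹.  Uniform
composition is an assumption (recorded in every report header), and random
sequences are not biological RNA: real molecules have biased composition,
correlated structure, and thermodynamics this scoring ignores.  Passing
tests therefore certify the *algorithms* — exactness of every engine
against the baseline and enumeration, the counter accounting, and the
relative engine ordering on this input model — not predictive accuracy on
real structures, and not the ordering on other input distributions.

## Numerical and design choices

* Integer arithmetic throughout; the −2⁴⁰ sentinel is far below any
  reachable score and safe to add to once without int64 overflow.
* Traceback works from L alone (valid for every engine, since restricted
  Lᵖ values differ only where they cannot matter), prefers the co-terminus
  case when it attains the optimum with a positive β, then the smallest
  split point; zero-scoring pairs are never emitted, so pair-free
  sequences yield empty structures.  Output is validated (non-crossing,
  disjoint, score = L[0,n]) before being returned.
* Signature bit order: offset x within a group carries value 2^x; any
  consistent order works for the dot product, this one is fixed for
  reproducibility.
* ε = 0.5 is accepted (the open-interval requirement matters only
  asymptotically) so that round block sizes like q = 4 at n = 256 are
  reachable.
* MUL tables are keyed by block coordinates, not block content, matching
  the per-submatrix accounting; content hashing would share entries across
  equal blocks but is deliberately left out.
* Degenerate inputs: n ≤ 1 returns score 0 with no work; q = 1 reduces the
  block engines to the cell-by-cell traversal with 1×1 table accesses.

## Problem sizes used in the shipped checks

The test suite verifies cross-engine matrix equality on 20 seeded sequences
at each n ∈ {16, 64, 128, 256}, enumeration agreement on 500 sequences with
n ≤ 12, and the engine-ordering property on the n ∈ {64, 128} suite; the
acceptance script reruns the 20-replicate benchmark at n ∈ {64, 128} plus
the exact baseline counts through n = 256.  These sizes keep a full run in
the low minutes on one core while covering several block-size regimes
(q = 1, 2, 3) and both partial-group geometries (q | n and not).

## Known limitations

* O(n²) memory per engine (plus tables); no memory sparsification.
* The parallel engine measures work, not wall-clock speedup; contention,
  memory bandwidth and synchronization costs are outside the model.
* The G table grows without bound by default (an LRU cap is not needed at
  these sizes); MUL/MAX tables are per-solve, never shared across calls.
* Counted-operation totals are convention-bound; only orderings and exact
  closed-form counts are meaningful across implementations.
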