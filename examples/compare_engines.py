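"""Run every engine on one random sequence and compare the work they count.

All five engines produce the identical optimal score (and identical score
matrix); they differ only in how many counted operations -- candidate
split-point evaluations plus lookup-table events -- they spend getting
there.  The combined sparse Four-Russians engine should cost at most the
cheaper of its two parent methods.
"""

from rnassf import ENGINES, random_sequence

seq = random_sequence(128, seed=7)
print(f"random sequence, n={seq.n}\n")
print(f"{'engine':14s} {'score':>5s} {'split':>8s} {'mulB':>6s} {'mulL':>6s} "
      f"{'maxB':>5s} {'gB':>4s} {'total':>8s}")
for name, solver in ENGINES.items():
    res = solver(seq, keep_dp=False)
    c = res.counters
    print(f"{name:14s} {res.score:5d} {c.split_comparisons:8d} {c.mul_builds:6d} "
          f"{c.mul_lookups:6d} {c.max_builds:5d} {c.g_builds:4d} {c.total():8d}")
print("\ntotal = split comparisons + table builds + gated MUL lookups;")
print("identical scores across rows are the cross-engine correctness check.")
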