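"""Simulate the per-column parallel algorithm and inspect its schedule.

One logical process per column advances one row group per synchronous
round; column j needs ceil((j+1)/q) rounds, so the whole matrix finishes in
n/q + 1 rounds instead of the serial n^2/q subvector steps.  The makespan
(the busiest column's counted operations) is the simulated parallel cost.
"""

from rnassf import random_sequence, solve_parallel_sim

seq = random_sequence(128, seed=3)
res = solve_parallel_sim(seq)
sched = res.params["schedule"]
work = sum(sched.ops_by_column.values())

print(f"n={seq.n}, block size q={sched.q}, score={res.score}")
print(f"rounds executed      : {sched.n_rounds}")
print(f"total counted work   : {work}")
print(f"makespan (busiest col): {sched.makespan}  "
      f"({sched.makespan / work:.1%} of the serial work)")
busy = max(sched.ops_by_column, key=sched.ops_by_column.get)
print(f"busiest column       : {busy} "
      f"(Z_j = {sched.oct_by_column[busy]} OCT cells)")

gated = solve_parallel_sim(seq, sparsified=True).params["schedule"]
print(f"sparsified makespan  : {gated.makespan} "
      f"(gating never increases any column's work)")
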