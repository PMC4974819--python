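"""The operation-count benchmark: 20 random sequences per size.

The cubic baseline's count is sequence independent -- exactly C(n+1, 3)
candidate split points per sequence (43,680 at n=64; 349,504 at n=128).
The other engines'
totals depend on the drawn sequences: sparsification exploits how few
sub-instances force their ends to pair, Four-Russians trades comparisons
for table events, and the combination beats both.
"""

from rnassf import run_benchmark

report = run_benchmark(sizes=[64, 128], reps=20, seed=1,
                       engines=["naive", "sp", "fr", "sfr"])
print("mean counted operations per sequence:\n")
print(report.per_sequence.round(0).to_string())
print("\nnaive column = C(n+1,3) exactly; sfr <= min(sp, fr) on every instance.")
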