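"""Folding under a richer integer scoring scheme (D-discrete case).

Any non-negative integer pair-score table works; here GC pairs are worth 3,
AU 2, and GU wobbles 1, so beta_max = 3 and column neighbors can differ by
up to 3.  The Four-Russians engines switch automatically to base-D
difference encoding (D = beta_max + 1 = 4).
"""

from rnassf import ScoringScheme, dotbracket, fold, normalize_sequence

scheme = ScoringScheme.from_pairs({"GC": 3, "AU": 2, "GU": 1})
seq = normalize_sequence("GGCAGUUCGAUGCC")

for engine in ("naive", "sfr"):
    res = fold(seq, engine=engine, scheme=scheme, q=2)
    print(f"{engine:6s}: score={res.score}  {dotbracket(seq, res.folding)}")
print("scores agree across engines; pairs are weighted, so the optimum can")
print("prefer fewer, stronger pairs over many weak ones.")
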