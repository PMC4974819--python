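"""Fold a single RNA sequence and print its optimal secondary structure.

The score is the maximum number of Watson-Crick pairs (AU/UA/CG/GC, one
point each) over all non-crossing structures; the dot-bracket line shows one
optimal structure, with matched parentheses marking the paired positions.
"""

from rnassf import dotbracket, fold, normalize_sequence

seq = normalize_sequence("GGGCUAUUAGCUCAGUUGGUUAGAGC")
res = fold(seq, engine="naive")

print(f"sequence ({seq.n} nt): {seq}")
print(f"optimal score       : {res.score} base pairs")
print(f"structure           : {dotbracket(seq, res.folding)}")
print(f"split comparisons   : {res.counters.split_comparisons}"
      f"  (cubic baseline examines C(n+1,3) candidates)")
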