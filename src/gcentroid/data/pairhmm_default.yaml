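# Default symmetric three-state pair HMM (states M = match, X = gap in y,
# Y = gap in x).  Transitions: match self-extension 0.9, gap opening 0.05 to
# each side; gap extension 0.3 with 0.65 back to match and 0.05 switching
# gap side.  The start distribution is reused as the end weights.
# Emissions are uniform over the alphabet (1/16 per residue pair in M,
# 1/4 per residue in X/Y for a 4-letter alphabet).
alphabet: ACGU
init:
  M: 0.9
  X: 0.05
  Y: 0.05
trans:
  M: {M: 0.9, X: 0.05, Y: 0.05}
  X: {M: 0.65, X: 0.3, Y: 0.05}
  Y: {M: 0.65, X: 0.05, Y: 0.3}
emissions: uniform
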