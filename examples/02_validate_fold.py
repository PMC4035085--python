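"""Validate the HDV-like ribozyme fold of candidate hallmark sequences.

Generates a descriptor-satisfying ribozyme, shows its helix assignment as a
layered dot-bracket string, then introduces the two structural defects
described for a weakly active natural signature -- a C1:A mismatch at the +1
position of helix P1 and a P2 helix trimmed to 3 bp -- and shows the coded
violations the validator reports.
"""

import pr77kit as pk
from pr77kit.fold import P1_MISMATCH_AT_PLUS1, P2_TOO_SHORT

rz = pk.sample_ribozyme(rng_seed=7, length=77)
res = pk.validate_hallmark(rz.seq)
print("sequence   :", rz.seq)
print("dot-bracket:", res.fold.dotbracket)
print("layers: () nested P1/P2/P4, [] pseudoknot P3, {} pseudoknot P1.1")
print(f"passes={res.passes}  helix lengths={res.fold.helix_lengths}  "
      f"P1 G:C run={res.fold.p1_gc_run}")

for code in (P1_MISMATCH_AT_PLUS1, P2_TOO_SHORT):
    broken = pk.break_constraint(rz.seq, rz.truth, code, rng_seed=1)
    r = pk.validate_hallmark(broken)
    print(f"\nafter breaking {code}: passes={r.passes}, violations={list(r.violations)}")

print(
    "\nA candidate passes only when P1, P2 and P4 plus both pseudoknots "
    "(P3, P1.1) can form with the required geometry."
)
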