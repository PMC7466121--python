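"""Which bases get misincorporated at m1A sites, and does the prebase matter?

Uses the package's built-in worked example: ten published m1A profile rows
(EpiScript, Mg reference buffer, S. cerevisiae total tRNA). The composition
merges forward and reverse counters, drops each position's reference base
and normalizes to 1 per stratum.
"""

from rtsig import ModificationAnnotation, mismatch_composition
from rtsig.datasets import example_m1a_profile

rows = example_m1a_profile()
ann = [ModificationAnnotation(r.ref_seg, r.pos, "m1A") for r in rows]

print("pooled composition over all ten m1A positions:")
print(mismatch_composition(rows, ann, "m1A").round(4))
print()
print("stratified by the 3'-preceding base (the base read just before the site):")
print(mismatch_composition(rows, ann, "m1A", group_by_prebase=True).round(4))
print()
print("The dominant misincorporated base tracks the prebase (T after T,")
print("C after C, G after G) — the slippage-like pattern the simulator's")
print("prebase_bias parameter reproduces.")
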