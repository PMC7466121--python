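"""Compare RT signatures between the Mg reference and a MnCl2-treated buffer.

Manganese lets the reverse transcriptase read through blocking modifications:
arrest collapses while misincorporation and nucleotide skipping rise. The
comparison matches positions across conditions and tests the per-position
deltas with a two-sided Wilcoxon signed-rank test.
"""

import dataclasses

from rtsig import (
    build_profiles,
    builtin_presets,
    compare_conditions,
    make_panel,
    simulate_library,
)

refs, ann = make_panel(n_refs=6, seed=4, length=76, sites=((58, "m1A"),))
presets = builtin_presets()

profiles = {}
for i, name in enumerate(("EpiScript_Mg_3mM", "EpiScript_Mn_3mM")):
    cond = dataclasses.replace(presets[name], n_molecules_per_ref=4000,
                               read_length=120, paired_fraction=0.0)
    reads, _ = simulate_library(refs, ann, cond, seed=10 + i)
    profiles[name] = build_profiles(reads, refs, ann)

for feature in ("arrest", "mismatch", "jump_total"):
    result = compare_conditions(profiles["EpiScript_Mg_3mM"],
                                profiles["EpiScript_Mn_3mM"],
                                ann, "m1A", feature, n_boot=2000, seed=0)
    flag = "*" if result.significant else " "
    print(
        f"m1A {feature:10s}: reference mean {result.reference.mean:.3f} "
        f"-> treated mean {result.treated.mean:.3f}, "
        f"mean delta {result.mean_delta:+.3f}, p={result.p_value:.3g} {flag}"
    )
print()
print("Asterisks mark p < 0.05 over the matched m1A positions. The arrest")
print("collapse (~0.82 -> ~0.24) with rising mismatch is the manganese effect")
print("the simulator presets encode.")
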