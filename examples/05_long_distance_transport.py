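"""In-silico radiolabel transport assays.

A fixed amount of auxin is deposited at one end of the root at t = 0 and the
deposit-derived (labelled) auxin arriving at the other end within an hour is
expressed relative to wild type.  Rootward transport drops in the abcb
mutants only when the ABCBs contribute to the polar efflux (scenario IV);
shootward transport drops in abcb4 wherever PIN needs ABCB.
"""

import rootflux as rf

template = rf.generate_regular_template()
dist = rf.build_distribution(template)

genos = {g: rf.genotype(g) for g in ("WT", "abcb1", "abcb19", "abcb1 abcb19")}
rootward = rf.long_distance_assay(template, genos, ["I", "IV"], "rootward", dist=dist)
print("rootward transport, normalized to WT:")
print(rootward.pivot(index="genotype", columns="scenario", values="normalized").round(3))

shootward = rf.long_distance_assay(
    template, {g: rf.genotype(g) for g in ("WT", "abcb4")},
    ["II", "IV", "V"], "shootward", dist=dist)
print("\nshootward transport, normalized to WT:")
print(shootward.pivot(index="genotype", columns="scenario", values="normalized").round(3))
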