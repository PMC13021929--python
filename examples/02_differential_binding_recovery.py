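"""Recover planted CUT&Tag occupancy shifts with differential binding.

Simulates the default experiment (300 planted elements, 3 replicates per
condition), counts fragments per true peak, runs the per-peak test, and
compares the estimated log2 fold changes with the planted truth.
"""

import numpy as np
from scipy import stats as sps

import cuttaggro as ctg

bundle = ctg.simulate_dataset(ctg.SimConfig(seed=1), preset="lce", gro=False)
frag_sets = bundle.cuttag["control"] + bundle.cuttag["treated"]

counts = ctg.count_fragments(frag_sets, bundle.peaks)
cpm = ctg.cpm_normalize(counts, {f.sample_id: f.library_size for f in frag_sets})
diff = ctg.differential_binding(
    cpm, {f.sample_id: f.condition for f in frag_sets}, "control", "treated"
)

truth = bundle.truth.elements.assign(
    peak_id="peak_" + bundle.truth.elements["element_id"]
)
merged = diff.set_index("peak_id").join(truth.set_index("peak_id"))
rho = sps.spearmanr(merged["log2fc"], merged["dlog2_occ"]).statistic
alt = merged["dlog2_occ"].abs() >= 1
sens = (merged.loc[alt, "fdr"] < 0.05).mean()
fpr = (merged.loc[merged["dlog2_occ"] == 0, "fdr"] < 0.05).mean()

print(f"peaks tested:                  {len(merged)}")
print(f"FRiP (first control replicate): {ctg.frip(frag_sets[0], bundle.peaks):.3f}")
print(f"rank corr est. vs planted lfc:  {rho:.3f}")
print(f"sensitivity (|shift|>=1, FDR<0.05): {sens:.3f}")
print(f"false-positive rate on nulls:   {fpr:.3f}")

# High rank correlation means the CPM + Welch-t + BH stand-in orders peaks by
# their true occupancy change; sensitivity/FPR summarize detection at FDR 0.05.
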