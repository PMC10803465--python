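"""Homoeolog expression bias: magnitude, calls and distribution summaries.

The 'magnitude' is the log2 ratio-of-ratios — how far the hybrid's T/K
homoeolog ratio deviates from the parental ortholog ratio.  A pair is
T-biased at magnitude > 1 (K-biased mirrored) with Fisher-exact p < 0.05
and BH FDR < 0.05.
"""

import homoeobias as hb

# one pair by hand: parents 1:1, allotetraploid 4:1 toward T
focal = hb.homoeolog_log2_ratio(80.0, 20.0)      # ~2 in log2
parent = hb.homoeolog_log2_ratio(50.0, 50.0)     # 0
mag = hb.magnitude(focal, parent)
p = hb.heb_test([80], [20], [50], [50])[0]
print(f"focal log2(T/K) = {focal:.3f}, parental = {parent:.3f}")
print(f"magnitude = {mag:.3f}, Fisher p = {p:.2e}")
print("-> a 4:1 homoeolog split against balanced parents is strong T-bias\n")

# study scale so distribution-shape statistics are stable (takes ~a minute)
bundle = hb.simulate(hb.SimConfig(n_pairs=5000, seed=7))
res = hb.run_analysis(
    bundle.counts, bundle.sheet, bundle.orthogroups, bundle.lengths,
    hb.PipelineConfig(),
)
print("bias calls per focal group (columns) over the analysis set:")
print(res.heb_call_counts.to_string())
print("\nlog2-ratio distribution summaries (one-sample t against 0):")
print(res.heb_distributions.round(3).to_string())
print(
    "\nKurtosis drops from parents to allotetraploid: planted bias broadens "
    "the\nratio distribution's mid-scale, exactly the pattern the magnitude "
    "statistic\nis designed to quantify."
)
print("\nstrong-bias tally in the allotetraploid (cutoff |magnitude| > 10):")
print(res.heb_strong["ALLO"].to_string())
print(f"\nshared HEB fraction F1K -> ALLO: {res.shared_heb_fraction:.3f}")
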