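"""Build the normalized polymerase-occupancy track.

The fusion library (polymerase-tethered Dam) is divided by the Dam-only
control, which cancels chromatin accessibility and sequencing depth at
once; the per-fragment log2 ratio is the occupancy signal.
"""

import numpy as np

import rapidfoot as rf

sim = rf.simulate_dataset(rf.SimParams.tiny(seed=1))
kept_f, _ = rf.filter_alignments(sim.fusion_reads, sim.index)
kept_c, _ = rf.filter_alignments(sim.control_reads, sim.index)
cf = rf.count_fragments(kept_f, sim.fragments, library_id="fusion")
cc = rf.count_fragments(kept_c, sim.fragments, library_id="control")

expressed = sim.truth.fragment_expression > 0
for scaling in ("library_size", "kde_mode"):
    track = rf.normalize_counts(
        cf, cc, rf.NormParams(pseudocount=0.5, scaling=scaling), fragments=sim.fragments
    )
    print(f"scaling = {scaling}")
    print(f"  median score (silent)   : {np.median(track.scores[~expressed]):+.3f}")
    print(f"  median score (expressed): {np.median(track.scores[expressed]):+.3f}")

print()
print("Expressed gene bodies carry a strong positive log2 footprint.")
print("Under plain library-size scaling the silent bulk sits below zero,")
print("because expressed genes soak up a large share of the fusion reads;")
print("kde_mode recenters the distribution so unbound chromatin reads ~0.")
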