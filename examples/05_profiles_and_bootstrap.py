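"""Metagene profile, ranked-bin expression comparison, and bootstrap TPR.

Three validation views: where along gene bodies the footprint sits, how
occupancy tracks mRNA abundance, and how a small reporter experiment
bounds the method's true positive rate.
"""

import pandas as pd

import rapidfoot as rf

sim = rf.simulate_dataset(rf.SimParams.tiny(seed=1))
kept_f, _ = rf.filter_alignments(sim.fusion_reads, sim.index)
kept_c, _ = rf.filter_alignments(sim.control_reads, sim.index)
cf = rf.count_fragments(kept_f, sim.fragments, library_id="fusion")
cc = rf.count_fragments(kept_c, sim.fragments, library_id="control")
track = rf.normalize_counts(cf, cc, fragments=sim.fragments)

# metagene: average occupancy on a TSS->TES-scaled grid
prof = rf.metagene(track, sim.genes, rf.ProfileParams(n_body_bins=50, flank_bp=500))
body = prof.mean_score[20:70]
print(f"metagene over {prof.n_genes} genes "
      f"({prof.n_skipped_short} skipped as shorter than the body grid)")
print(f"  upstream flank mean : {prof.mean_score[:20].mean():+.3f}")
print(f"  gene body mean      : {body.mean():+.3f}")

# ranked bins: occupancy rank vs simulated expression level
scores = rf.gene_occupancy(track, sim.genes)
tpm = pd.DataFrame({
    "gene_id": sim.truth.expression["gene_id"],
    "tpm": sim.truth.expression["expression"],
})
bins = rf.ranked_bin_comparison(scores, tpm, rf.ProfileParams(bin_size_genes=10))
print()
print("occupancy-rank bins (10 genes each) -> mean expression:")
for row in bins.itertuples(index=False):
    print(f"  bin {row.bin}: occupancy [{row.occupancy_min:+.2f}, "
          f"{row.occupancy_max:+.2f}]  mean level {row.mean_tpm:7.2f}")

# bootstrap TPR from a reporter validation: 8 positives of 11 tested
res = rf.bootstrap_tpr(8, 11, rf.BootstrapParams(n_boot=100_000, seed=1))
lo, hi = rf.extrapolate_expressed(res, 2362, rounding="nearest_100")
print()
print(f"TPR {res.point_estimate:.2f}, 95% CI [{res.ci_lower:.3f}, {res.ci_upper:.3f}]")
print(f"extrapolated over 2362 detected genes: {lo}-{hi} truly expressed")
print()
print("Low bins hold silent genes; expression rises with occupancy rank")
print("and flattens at the top, the methylation-saturation plateau.")
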