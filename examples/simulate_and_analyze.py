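"""Simulate a small immunoarray experiment and screen for differentially
reactive peptides.

Generates 101 tiled 15-mer peptides (triplicate spots) for 4 control and
4 treatment sera with 5% of peptides spiked in the treatment cohort,
then runs the synoptic pipeline: background-scaled intensities, median
replicate aggregation, quantile normalization, per-peptide Mann-Whitney
U tests with Benjamini-Hochberg correction.
"""

import peparray as pa

spec = pa.SimSpec(seed=1, protein_length=415, n_control=4, n_treatment=4)
samples, truth = pa.simulate_samples(spec)
matrix = pa.assemble_matrix(samples, mode="background_scale")
matrix = pa.quantile_normalize(matrix)
table = pa.build_synoptic_table(matrix)

sel = pa.select_subset(table, pa.SubsetSpec(cutoff=20, direction="up", fdr=0.25))
top = table.data.set_index("spot_id").loc[sel.by_effect[:5]]
print(f"peptides tested: {len(table)}   true spiked: {sorted(truth.differential_ids)}")
print("top 5 by effect size (direction up):")
print(top[["delta_rfu", "p_raw", "p_adj"]].round(4).to_string())
# delta_rfu > 0 means stronger antibody reactivity in the treatment
# cohort; the largest effects coincide with the spiked peptides.  With
# only 4+4 samples the smallest attainable exact p is 2/70, so adjusted
# p-values stay moderate even for true spikes — the rank-cutoff rules
# exist precisely to screen candidates under such conditions.
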