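"""Generate a synthetic seasonal-methylation cohort and write it to disk.

The cohort emulates a year-round-conception child study: beta-valued
methylation at 2000 array CpGs, 50 of which carry a sinusoidal
conception-date effect (~6% beta amplitude peaking in early September),
plus covariate/batch/cell-composition structure, genotypes with spiked
cis-mQTL, clustered CpG coordinates, and an annotation track enriched
near the seasonal CpGs.
"""

import socmeth as sm
from socmeth import io

cfg = sm.SimConfig(seed=1)
cohort = sm.simulate_cohort(cfg)

print(f"samples:              {cohort.methylation.n_samples}")
print(f"CpGs:                 {len(cohort.methylation.cpg_ids)}")
print(f"seasonal (hit) CpGs:  {int(cohort.truth['is_hit'].sum())}")
print(f"SNPs (incl. spikes):  {cohort.genotypes.n_snps}")
hits = cohort.truth[cohort.truth["is_hit"]]
print(f"true beta amplitude:  median {hits['amplitude_beta_pct'].median():.2f}% "
      f"(range {hits['amplitude_beta_pct'].min():.2f}-{hits['amplitude_beta_pct'].max():.2f}%)")
print(f"true peak day:        {hits['peak_day'].iloc[0]:.0f} (day of year; 244 = early September)")

io.write_cohort(cohort, "scratch/example_cohort")
print("cohort written to scratch/example_cohort/ "
      "(methylation.tsv, metadata.csv, dosages.tsv, genotypes.vcf, BED tracks, truth.tsv)")
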