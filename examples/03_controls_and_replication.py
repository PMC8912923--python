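"""Matched/random controls and cross-dataset replication statistics.

The same simulated individuals are re-measured at an older age with the
seasonal amplitude halved — emulating attenuation of the
conception-season effect. The replication report gives the Spearman
correlation of per-CpG peak days across the two measurements and a
Wilcoxon signed-rank test on the paired amplitude change.
"""

import socmeth as sm

# peak_day=None: each seasonal CpG gets its own peak day, so peak-day
# concordance across datasets is informative
cfg = sm.SimConfig(seed=1, peak_day=None)
young = sm.simulate_cohort(cfg)
old = sm.simulate_followup(young, amplitude_scale=0.5, seed=2)


def analyse(cohort):
    pcs = sm.compute_pcs(sm.beta_to_m(cohort.methylation.betas.to_numpy()), 6)
    cov = sm.build_covariates(cohort.metadata.frame, pcs=pcs)
    return sm.run_ewas(cohort.methylation, cohort.metadata, cov)


ewas_young = analyse(young)
ewas_old = analyse(old)
hits = sm.select_soc_cpgs(ewas_young)
print(f"hits in the younger dataset: {len(hits)}")

matched = sm.select_matched_controls(hits, young.methylation.betas, seed=3)
random_ctl = sm.select_random_controls(len(hits), young.methylation.betas,
                                       exclusions=[hits, matched], seed=3)
sm.hits.assert_disjoint(hits, matched, random_ctl)
print(f"matched controls (KS p>0.1 vs each hit): {len(matched)}; "
      f"random controls: {len(random_ctl)}")

rep = sm.replication_stats(ewas_young, ewas_old, hits)
print(f"\nreplication over {rep.n_shared} shared CpGs:")
print(f"  peak-day Spearman rho = {rep.peak_day_rho:.2f} (p = {rep.peak_day_p:.2e})"
      "  -> seasonal phase agrees across measurements")
print(f"  amplitude change: median {rep.amplitude_deltas.median():.2f} "
      f"percentage points (Wilcoxon p = {rep.wilcoxon_p:.2e})"
      "  -> the effect attenuates with age")
print(f"  CpGs still significant (q<5%) at the older age: {rep.n_replicated}")

rep_ctl = sm.replication_stats(ewas_young, ewas_old, matched)
print(f"  matched controls: rho = {rep_ctl.peak_day_rho:.2f}, "
      f"Wilcoxon p = {rep_ctl.wilcoxon_p:.2f}"
      "  -> no phase agreement and no amplitude change at non-seasonal CpGs")
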