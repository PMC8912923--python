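"""Genomic context of seasonal hits: clusters, enrichment, gametes.

Hits are clustered at 5 kbp, tested for annotation-track enrichment
(two-sided Fisher exact), re-tested after de-clustering (one CpG per
cluster), summarised as a proximity curve with bootstrap CIs, and a few
CpGs are classified by their gametic methylation.
"""

import socmeth as sm

cohort = sm.simulate_cohort(sm.SimConfig(seed=1))
hits = sm.CpGSet("soc_cpg", list(cohort.truth.index[cohort.truth["is_hit"]]))
coords = cohort.methylation.cpg_info
background = cohort.methylation.cpg_ids
track = cohort.tracks[0]

clusters = sm.build_clusters(coords.loc[hits.cpg_ids], max_gap_bp=5000)
n_multi = sum(1 for c in clusters if not c.is_singleton)
print(f"hit CpGs: {len(hits)}; clusters: {n_multi} multi-CpG + "
      f"{sum(c.is_singleton for c in clusters)} singletons")

raw = sm.overlap_enrichment(hits, track, background, coords)
adj = sm.cluster_adjusted_enrichment(hits, track, background, coords,
                                     n_draws=50, seed=4)
print(f"track enrichment: {raw.fold:.1f}-fold (p = {raw.p_value:.2e}); "
      f"cluster-adjusted: {adj.fold:.1f}-fold (p = {adj.p_value:.2e})")
print("  (the generator placed the track at 10-fold enrichment over background)")

curve = sm.proximity_curve(hits, coords, track, [100, 5000, 50_000],
                           n_boot=1000, seed=5)
print("\nproportion of (de-clustered) hits within d bp of the track:")
for _, row in curve.iterrows():
    print(f"  d = {int(row['distance']):>5}: {row['proportion']:.2f} "
          f"[95% CI {row['ci_low']:.2f}, {row['ci_high']:.2f}]")

print("\ngametic methylation classification (sperm %, oocyte %):")
for sperm, oocyte in [(10, 90), (90, 10), (20, 50), (30, 40)]:
    status = sm.classify_gamete_status(sperm, oocyte).status
    print(f"  ({sperm:>2}, {oocyte:>2}) -> {status}")
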