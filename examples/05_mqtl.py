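"""Genetic influence on seasonal CpGs: cis/trans mQTL, variance, GxE.

The simulated cohort spikes a cis SNP (within 1 Mb) at half of the
seasonal CpGs. The two-step scan finds them, the variance decomposition
quantifies how much methylation variance the genotype explains beyond
the covariates, and the season-genotype check confirms the genetic and
seasonal influences are independent.
"""

import pandas as pd

import socmeth as sm

cohort = sm.simulate_cohort(sm.SimConfig(seed=1))
truth = cohort.truth
spiked = truth.index[truth["mqtl_snp"].notna()]

pcs = sm.compute_pcs(sm.beta_to_m(cohort.methylation.betas.to_numpy()), 6)
covariates = sm.build_covariates(cohort.metadata.frame, pcs=pcs)
genotypes = sm.filter_snps(cohort.genotypes)
print(f"SNPs passing MAF>10% and >=10-homozygote filters: "
      f"{genotypes.n_snps}/{cohort.genotypes.n_snps}")

m_values = pd.DataFrame(sm.beta_to_m(cohort.methylation.betas[spiked].to_numpy()),
                        index=cohort.methylation.betas.index, columns=spiked)
records = sm.mqtl_scan(m_values, genotypes, covariates,
                       cohort.methylation.cpg_info.loc[spiked])
sig = sm.significant_mqtl(records)
n_cis = (sig["scope"] == "cis").sum()
print(f"significant mQTL (FDR<5%): {len(sig)} ({n_cis} cis) "
      f"across {sig['cpg_id'].nunique()}/{len(spiked)} spiked CpGs")

cpg = spiked[0]
snps = sig.loc[sig["cpg_id"] == cpg, "snp_id"].tolist()
rep = sm.variance_explained(m_values[cpg], genotypes.dosages[snps],
                            covariates, cpg_id=cpg)
print(f"{cpg}: {rep.n_mqtl} mQTL explain delta-adjR2 = {rep.delta_adj_r2:.3f} "
      "of methylation variance beyond covariates")

main_fit = sm.fit_cosinor(m_values[cpg], cohort.metadata["theta"].to_numpy(),
                          covariates, cpg_id=cpg)
gxe = sm.gxe_scan(m_values[cpg], genotypes, cohort.metadata["theta"].to_numpy(),
                  covariates, main_fit)
print(f"GxE scan at {cpg} ({gxe['term'].iloc[0]} term): "
      f"min interaction q = {gxe['q'].min():.2f} "
      "(no interaction was simulated, so nothing should pass)")

soc = sm.soc_genotype_association(genotypes, cohort.metadata, mode="regression")
n_pass = int((soc["q"] < 0.05).sum())
print(f"season-genotype association: {n_pass}/{len(soc)} SNPs at FDR<5% "
      f"(min p = {soc['p'].min():.1e}). Genotypes were simulated "
      "independently of conception dates, so any discovery here is a "
      "false positive; a real analysis would treat survivors as "
      "candidate confounders of the seasonal methylation signal.")
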