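import numpy as np
import pandas as pd
import pytest
from scipy import stats

import socmeth as sm
from socmeth.mqtl import GenotypeMatrix, _adj_r2, _design_with_intercept


def _geno_from_dosages(dosages: dict, chrom="chr1", pos_start=1000):
    df = pd.DataFrame(dosages)
    df.index = [f"S{i}" for i in range(len(df))]
    info = pd.DataFrame({
        "chrom": [chrom] * df.shape[1],
        "pos": np.arange(pos_start, pos_start + df.shape[1]),
    }, index=df.columns)
    return GenotypeMatrix(dosages=df, info=info)


class TestSnpFilters:
    def test_maf_exactly_ten_percent_removed(self):
        # 100 samples, 20 alt alleles -> MAF = 0.10, not > 0.10
        g = [2] * 10 + [0] * 90
        gm = _geno_from_dosages({"snp_a": g, "snp_b": [1] * 50 + [0, 2] * 25})
        kept = sm.filter_snps(gm)
        assert "snp_a" not in kept.dosages.columns
        assert "snp_b" in kept.dosages.columns

    def test_few_homozygotes_removed(self):
        # MAF fine but only 9 homozygous carriers (all dosage-2; every
        # dosage-0 sample replaced by heterozygotes)
        g = [2] * 9 + [1] * 91
        gm = _geno_from_dosages({"snp_a": g})
        assert gm.info.loc["snp_a", "n_hom"] == 9
        assert len(sm.filter_snps(gm).dosages.columns) == 0

    def test_common_snp_retained(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, 200)
        gm = _geno_from_dosages({"snp_a": g})
        assert "snp_a" in sm.filter_snps(gm).dosages.columns

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValueError):
            _geno_from_dosages({"snp_a": [0, 1, 3, 2]})


class TestCisTransLabelling:
    @pytest.mark.parametrize("dist,expected", [
        (999_999, "cis"), (1_000_000, "cis"), (1_000_001, "trans")])
    def test_window_boundary(self, dist, expected):
        assert sm.is_cis("chr1", 5_000_000, "chr1", 5_000_000 + dist) == (expected == "cis")

    def test_different_chromosome_is_trans(self):
        assert not sm.is_cis("chr1", 100, "chr2", 100)

    def test_scan_labels_flip_at_boundary(self):
        rng = np.random.default_rng(1)
        n = 120
        g_near = rng.binomial(2, 0.3, n)
        g_far = rng.binomial(2, 0.3, n)
        dosages = pd.DataFrame({"near": g_near, "far": g_far},
                               index=[f"S{i:04d}" for i in range(n)])
        info = pd.DataFrame({"chrom": ["chr1", "chr1"],
                             "pos": [5_000_000 + 1_000_000, 5_000_000 + 1_000_001]},
                            index=["near", "far"])
        gm = GenotypeMatrix(dosages=dosages, info=info)
        m = pd.DataFrame({"cpg1": rng.normal(size=n)}, index=dosages.index)
        cpg_pos = pd.DataFrame({"chrom": ["chr1"], "pos": [5_000_000]}, index=["cpg1"])
        rec = sm.mqtl_scan(m, gm, None, cpg_pos)
        scope = rec.set_index("snp_id")["scope"]
        assert scope["near"] == "cis" and scope["far"] == "trans"

    def test_effect_identical_to_joint_ols(self):
        rng = np.random.default_rng(2)
        n = 150
        g = rng.binomial(2, 0.4, n)
        cov = pd.DataFrame({"sex": rng.integers(0, 2, n)},
                           index=[f"S{i:04d}" for i in range(n)])
        y = 0.2 * g + 0.1 * cov["sex"].to_numpy() + rng.normal(0, 0.3, n)
        m = pd.DataFrame({"cpg1": y}, index=cov.index)
        gm = GenotypeMatrix(
            dosages=pd.DataFrame({"snp": g}, index=cov.index),
            info=pd.DataFrame({"chrom": ["chr1"], "pos": [1000]}, index=["snp"]))
        cpg_pos = pd.DataFrame({"chrom": ["chr1"], "pos": [2000]}, index=["cpg1"])
        rec = sm.mqtl_scan(m, gm, cov, cpg_pos)
        X = np.column_stack([np.ones(n), cov["sex"], g])
        ref = np.linalg.solve(X.T @ X, X.T @ y)[-1]
        assert rec.loc[0, "effect"] == pytest.approx(ref, abs=1e-10)

    def test_null_scan_fdr_controls_discoveries(self):
        rng = np.random.default_rng(3)
        n = 100
        gm = sm.simulate_genotypes(n, 40, seed=4)
        m = pd.DataFrame(rng.normal(size=(n, 10)),
                         index=gm.dosages.index,
                         columns=[f"cpg{i}" for i in range(10)])
        cpg_pos = pd.DataFrame({"chrom": ["chr9"] * 10,
                                "pos": np.arange(10) * 10_000 + 1},
                               index=m.columns)
        rec = sm.mqtl_scan(m, gm, None, cpg_pos)
        assert len(sm.significant_mqtl(rec)) <= 2


class TestVarianceExplained:
    def test_zero_effect_snp_adds_nothing(self):
        rng = np.random.default_rng(5)
        n = 1000
        g = pd.DataFrame({"snp": rng.binomial(2, 0.3, n)})
        y = rng.normal(size=n)
        rep = sm.variance_explained(y, g, None)
        assert abs(rep.delta_adj_r2) < 0.01

    def test_requires_at_least_one_snp(self):
        with pytest.raises(ValueError):
            sm.variance_explained(np.zeros(10), pd.DataFrame(index=range(10)), None)

    def test_too_many_regressors_error(self):
        rng = np.random.default_rng(6)
        g = pd.DataFrame(rng.binomial(2, 0.3, size=(10, 12)))
        with pytest.raises(ValueError):
            sm.variance_explained(rng.normal(size=10), g, None)

    def test_delta_matches_direct_adjusted_r2_formula(self):
        rng = np.random.default_rng(7)
        n = 60
        cov = pd.DataFrame({"age": rng.normal(size=n)})
        g = pd.DataFrame({"snp": rng.binomial(2, 0.4, n)})
        y = 0.4 * g["snp"].to_numpy() + 0.2 * cov["age"].to_numpy() + rng.normal(size=n)
        rep = sm.variance_explained(y, g, cov)

        def brute_adj_r2(X):
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            r2 = 1 - np.sum((y - X @ coef) ** 2) / np.sum((y - y.mean()) ** 2)
            return 1 - (1 - r2) * (n - 1) / (n - X.shape[1])

        Xc = _design_with_intercept(cov, n)
        Xf = np.hstack([Xc, g.to_numpy(dtype=float)])
        assert rep.delta_adj_r2 == pytest.approx(brute_adj_r2(Xf) - brute_adj_r2(Xc),
                                                 abs=1e-12)

    def test_spiked_snp_variance_recovered(self):
        rng = np.random.default_rng(8)
        deltas = []
        for rep in range(30):
            n = 284
            g = rng.binomial(2, 0.3, n)
            y = 0.146 * (g - g.mean()) + rng.normal(0, 0.3, n)
            out = sm.variance_explained(y, pd.DataFrame({"snp": g}), None)
            deltas.append(out.delta_adj_r2)
        assert 0.06 <= np.median(deltas) <= 0.12


class TestGxE:
    def _inputs(self, n=200, seed=9, interaction=0.0):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 2 * np.pi, n)
        g = rng.binomial(2, 0.3, n)
        y = 0.2 * np.sin(theta) + 0.1 * g + interaction * g * np.sin(theta) \
            + rng.normal(0, 0.3, n)
        gm = GenotypeMatrix(
            dosages=pd.DataFrame({"snp": g}, index=[f"S{i}" for i in range(n)]),
            info=pd.DataFrame({"chrom": ["chr1"], "pos": [100]}, index=["snp"]))
        return y, gm, theta

    def test_most_significant_term_selected(self):
        y, gm, theta = self._inputs()
        fit_sin = sm.CosinorFit("c", 0, 0, 0, sin_p=0.001, cos_p=0.5)
        fit_cos = sm.CosinorFit("c", 0, 0, 0, sin_p=0.5, cos_p=0.001)
        fit_tie = sm.CosinorFit("c", 0, 0, 0, sin_p=0.1, cos_p=0.1)
        assert sm.gxe_scan(y, gm, theta, None, fit_sin)["term"].iloc[0] == "sin"
        assert sm.gxe_scan(y, gm, theta, None, fit_cos)["term"].iloc[0] == "cos"
        assert sm.gxe_scan(y, gm, theta, None, fit_tie)["term"].iloc[0] == "sin"

    def test_null_interaction_calibrated(self):
        rng = np.random.default_rng(10)
        fit = sm.CosinorFit("c", 0, 0, 0, sin_p=0.01, cos_p=0.5)
        n = 150
        rejections = 0
        n_tests = 400
        for i in range(n_tests):
            theta = rng.uniform(0, 2 * np.pi, n)
            g = rng.binomial(2, 0.3, n)
            y = 0.2 * np.sin(theta) + 0.1 * g + rng.normal(0, 0.3, n)
            gm = GenotypeMatrix(
                dosages=pd.DataFrame({"snp": g}, index=[f"S{i}" for i in range(n)]),
                info=pd.DataFrame({"chrom": ["chr1"], "pos": [100]}, index=["snp"]))
            if sm.gxe_scan(y, gm, theta, None, fit)["p"].iloc[0] < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_tests <= 0.08

    def test_spiked_interaction_detected(self):
        detected = 0
        for rep in range(20):
            y, gm, theta = self._inputs(n=284, seed=100 + rep, interaction=0.25)
            fit = sm.CosinorFit("c", 0, 0, 0, sin_p=0.001, cos_p=0.5)
            if sm.gxe_scan(y, gm, theta, None, fit)["p"].iloc[0] < 0.05:
                detected += 1
        assert detected / 20 > 0.8


class TestSocGenotypeAssociation:
    def _meta(self, theta):
        import datetime as dt
        days = (theta / (2 * np.pi) * 365).astype(int)
        dates = [dt.date(2011, 1, 1) + dt.timedelta(days=int(d)) for d in days]
        frame = pd.DataFrame({"conception_date": dates},
                             index=[f"S{i}" for i in range(len(dates))])
        return sm.SampleMetadata(frame)

    def test_null_genotypes_calibrated(self):
        rng = np.random.default_rng(11)
        n = 284
        theta = rng.uniform(0, 2 * np.pi, n)
        gm = sm.simulate_genotypes(n, 200, seed=12)
        gm.dosages.index = [f"S{i}" for i in range(n)]
        out = sm.soc_genotype_association(gm, self._meta(theta), mode="regression")
        rate = (out["p"] < 0.05).mean()
        assert 0.01 <= rate <= 0.09

    def test_seasonal_dosage_detected(self):
        rng = np.random.default_rng(13)
        n = 284
        theta = rng.uniform(0, 2 * np.pi, n)
        # dosage correlated with sin(theta) at r ~ 0.3
        latent = 0.3 * np.sin(theta) + np.sqrt(1 - 0.09) * rng.normal(size=n)
        g = np.clip(np.round(latent + 1.0), 0, 2).astype(int)
        gm = GenotypeMatrix(
            dosages=pd.DataFrame({"snp": g}, index=[f"S{i}" for i in range(n)]),
            info=pd.DataFrame({"chrom": ["chr1"], "pos": [100]}, index=["snp"]))
        out = sm.soc_genotype_association(gm, self._meta(theta), mode="regression")
        assert out["p"].iloc[0] < 0.001

    def test_dichotomised_matches_textbook_chi_square(self):
        # hand-built 2x2 allele table: rainy 30 alt / 70 ref,
        # dry 10 alt / 90 ref
        import datetime as dt
        dates, dosages = [], []
        for alt, total, start in ((15, 50, dt.date(2011, 8, 1)),
                                  (5, 50, dt.date(2011, 2, 1))):
            for i in range(total):
                dates.append(start)
                dosages.append(2 if i < alt else 0)
        frame = pd.DataFrame({"conception_date": dates},
                             index=[f"S{i}" for i in range(100)])
        gm = GenotypeMatrix(
            dosages=pd.DataFrame({"snp": dosages}, index=frame.index),
            info=pd.DataFrame({"chrom": ["chr1"], "pos": [100]}, index=["snp"]))
        out = sm.soc_genotype_association(
            gm, sm.SampleMetadata(frame), mode="dichotomised",
            season_windows={"rainy": (150, 300), "dry": (0, 120)})
        table = np.array([[30, 70], [10, 90]])
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((table - exp) ** 2 / exp).sum()
        p_ref = stats.chi2.sf(chi2, 1)
        assert out["p"].iloc[0] == pytest.approx(p_ref, rel=1e-9)

    def test_empty_season_group_errors(self):
        theta = np.array([0.1, 0.2, 0.3])
        gm = GenotypeMatrix(
            dosages=pd.DataFrame({"snp": [0, 1, 2]}, index=["S0", "S1", "S2"]),
            info=pd.DataFrame({"chrom": ["chr1"], "pos": [100]}, index=["snp"]))
        with pytest.raises(ValueError):
            sm.soc_genotype_association(
                gm, self._meta(theta), mode="dichotomised",
                season_windows={"rainy": (200, 250), "dry": (0, 100)})


class TestEndToEndMqtl:
    def test_spiked_cohort_cis_mqtl_recovered(self):
        cfg = sm.SimConfig(n_samples=200, n_cpgs=300, n_hit_cpgs=10,
                           mqtl_hit_fraction=1.0, seed=21)
        cohort = sm.simulate_cohort(cfg)
        truth = cohort.truth
        spiked = truth.index[truth["mqtl_snp"].notna()]
        m = pd.DataFrame(
            sm.beta_to_m(cohort.methylation.betas[spiked].to_numpy()),
            index=cohort.methylation.betas.index, columns=spiked)
        pcs = sm.compute_pcs(sm.beta_to_m(cohort.methylation.betas.to_numpy()), 6)
        cov = sm.build_covariates(cohort.metadata.frame, pcs=pcs)
        rec = sm.mqtl_scan(m, sm.filter_snps(cohort.genotypes), cov,
                           cohort.methylation.cpg_info.loc[spiked])
        sig = sm.significant_mqtl(rec)
        found = 0
        for cpg in spiked:
            snp = truth.loc[cpg, "mqtl_snp"]
            hit = sig[(sig.cpg_id == cpg) & (sig.snp_id == snp)]
            if len(hit):
                found += 1
                assert (hit["scope"] == "cis").all()
        assert found >= 8
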