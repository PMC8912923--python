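"""Genetic influence on methylation: mQTL mapping, variance, GxE.

SNP effects on methylation are modelled per (CpG, SNP) pair as
``M_j ~ covariates + G`` with G the allelic dosage (0/1/2). To maximise
power, mapping is two-step: a *cis* screen restricted to SNPs within a
window (default 1 Mb) of each CpG with BH-FDR within that family, then a
*trans* screen over all SNPs with BH-FDR over the full family. Variance
explained by the significant mQTL of a CpG is summarised as the gain in
adjusted R-squared over the covariate-only model. A gene-by-season scan
tests a SNP-by-Fourier-term interaction, and a season-genotype
association check guards against genetic confounding of the seasonal
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import fdr_adjust
from .preprocess import conception_theta

CIS_WINDOW_BP = 1_000_000
MIN_MAF = 0.10
MIN_HOMOZYGOTES = 10


@dataclass
class GenotypeMatrix:
    """Allelic dosages (samples x SNPs, values 0/1/2) plus SNP metadata.

    ``info`` is indexed by SNP id with ``chrom`` and ``pos`` columns;
    ``maf`` and ``n_hom`` are (re)computed from the dosages.
    """

    dosages: pd.DataFrame
    info: pd.DataFrame

    def __post_init__(self):
        vals = self.dosages.to_numpy()
        if not np.isin(vals, [0, 1, 2]).all():
            raise ValueError("dosages must be in {0, 1, 2}")
        freq = vals.mean(axis=0) / 2.0
        self.info = self.info.copy()
        self.info["maf"] = np.minimum(freq, 1.0 - freq)
        self.info["n_hom"] = ((vals == 0) | (vals == 2)).sum(axis=0)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


def filter_snps(genotypes: GenotypeMatrix, min_maf: float = MIN_MAF,
                min_hom: int = MIN_HOMOZYGOTES) -> GenotypeMatrix:
    """Drop SNPs failing the MAF and homozygote-count filters.

    SNPs with empirical MAF <= ``min_maf`` are excluded, as are SNPs
    with fewer than ``min_hom`` homozygous (dosage 0 or 2) carriers —
    low-frequency homozygotes exert undue leverage in linear models.
    """
    keep = (genotypes.info["maf"] > min_maf) & (genotypes.info["n_hom"] >= min_hom)
    kept = genotypes.info.index[keep]
    return GenotypeMatrix(dosages=genotypes.dosages[kept],
                          info=genotypes.info.loc[kept, ["chrom", "pos"]])


def is_cis(cpg_chrom, cpg_pos, snp_chrom, snp_pos,
           window_bp: int = CIS_WINDOW_BP) -> bool:
    """Pure coordinate predicate: same chromosome and within the window
    (inclusive at exactly ``window_bp``)."""
    return (cpg_chrom == snp_chrom) and abs(int(cpg_pos) - int(snp_pos)) <= window_bp


def _residualise(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of each column of Y on the design X (with intercept)."""
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ coef


def _design_with_intercept(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(pd.DataFrame(covariates), dtype=float)
    return np.hstack([np.ones((n, 1)), C])


def _pairwise_assoc(M_resid: np.ndarray, G_resid: np.ndarray, dof: int):
    """Per-pair effect, t and p for methylation ~ covs + G via
    Frisch-Waugh partialling: both sides residualised on the covariates,
    then simple regression slope and its t-test with covariate-adjusted
    degrees of freedom. Exact match to the full joint OLS."""
    gss = np.einsum("ij,ij->j", G_resid, G_resid)
    cross = M_resid.T @ G_resid                      # cpgs x snps
    mss = np.einsum("ij,ij->j", M_resid, M_resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = cross / gss[None, :]
        r2 = cross ** 2 / (mss[:, None] * gss[None, :])
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        tstat = np.sign(beta) * np.sqrt(r2 * dof / (1.0 - r2))
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return beta, p


def mqtl_scan(m_values: pd.DataFrame, genotypes: GenotypeMatrix,
              covariates, cpg_positions: pd.DataFrame,
              cis_window_bp: int = CIS_WINDOW_BP) -> pd.DataFrame:
    """Two-step cis/trans mQTL scan over a set of CpGs.

    Step 1 tests each CpG against same-chromosome SNPs within
    ``cis_window_bp`` and applies BH-FDR within the pooled cis family.
    Step 2 tests all SNPs with BH-FDR over the full family; only pairs
    outside the cis window are emitted from this step (labelled trans).
    Effect estimates are identical in both steps — the model does not
    depend on the family.

    Parameters
    ----------
    m_values : DataFrame
        Samples x CpGs M-values (the CpGs to scan, e.g. seasonal hits).
    genotypes : GenotypeMatrix
        Pre-filtered dosages aligned to the same samples.
    covariates : DataFrame or None
        Adjustment covariates (the same set as the seasonal analysis).
    cpg_positions : DataFrame
        chrom/pos per scanned CpG.

    Returns
    -------
    DataFrame with columns cpg_id, snp_id, scope, effect, p, q. ``q`` is
    the within-family BH value (cis family for cis rows, full family for
    trans rows).
    """
    if not m_values.index.equals(genotypes.dosages.index):
        raise ValueError("sample IDs of methylation and genotypes differ")
    n = m_values.shape[0]
    X = _design_with_intercept(covariates, n)
    dof = n - X.shape[1] - 1
    M_resid = _residualise(np.asarray(m_values, float), X)
    G_resid = _residualise(np.asarray(genotypes.dosages, float), X)
    beta, p = _pairwise_assoc(M_resid, G_resid, dof)

    cpg_ids = list(m_values.columns)
    snp_ids = list(genotypes.dosages.columns)
    cpg_chrom = cpg_positions.loc[cpg_ids, "chrom"].to_numpy()
    cpg_pos = cpg_positions.loc[cpg_ids, "pos"].to_numpy()
    snp_chrom = genotypes.info.loc[snp_ids, "chrom"].to_numpy()
    snp_pos = genotypes.info.loc[snp_ids, "pos"].to_numpy()
    same_chrom = cpg_chrom[:, None] == snp_chrom[None, :]
    dist_ok = np.abs(cpg_pos[:, None].astype(np.int64)
                     - snp_pos[None, :].astype(np.int64)) <= cis_window_bp
    cis_mask = same_chrom & dist_ok

    rows = []
    ci, cj = np.nonzero(cis_mask)
    if len(ci):
        q_cis = fdr_adjust(p[ci, cj])
        for idx in range(len(ci)):
            rows.append((cpg_ids[ci[idx]], snp_ids[cj[idx]], "cis",
                         beta[ci[idx], cj[idx]], p[ci[idx], cj[idx]], q_cis[idx]))
    q_all = fdr_adjust(p.ravel()).reshape(p.shape)
    ti, tj = np.nonzero(~cis_mask)
    for idx in range(len(ti)):
        rows.append((cpg_ids[ti[idx]], snp_ids[tj[idx]], "trans",
                     beta[ti[idx], tj[idx]], p[ti[idx], tj[idx]], q_all[ti[idx], tj[idx]]))
    return pd.DataFrame(rows, columns=["cpg_id", "snp_id", "scope", "effect", "p", "q"])


def significant_mqtl(records: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Rows passing the within-family FDR threshold."""
    return records[records["q"] < fdr_threshold].reset_index(drop=True)


def _adj_r2(y: np.ndarray, X: np.ndarray) -> float:
    n, p = X.shape  # p includes the intercept
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p)


def variance_explained(m_values, mqtl_dosages: pd.DataFrame,
                       covariates, cpg_id: str = "") -> "VarianceReport":
    """Methylation variance explained by a CpG's mQTL.

    Delta adjusted R-squared between the covariates + all-mQTL model and
    the covariate-only model on identical samples. Adjusted R-squared is
    used so that CpGs with many mQTL are not mechanically favoured; the
    delta can be slightly negative for uninformative SNPs.
    """
    G = np.asarray(mqtl_dosages, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if G.shape[1] < 1:
        raise ValueError("at least one mQTL dosage column is required")
    y = np.asarray(m_values, dtype=float)
    n = len(y)
    Xc = _design_with_intercept(covariates, n)
    Xf = np.hstack([Xc, G])
    if Xf.shape[1] >= n:
        raise ValueError("more regressors than samples")
    delta = _adj_r2(y, Xf) - _adj_r2(y, Xc)
    return VarianceReport(cpg_id=cpg_id, n_mqtl=G.shape[1], delta_adj_r2=float(delta))


@dataclass
class VarianceReport:
    cpg_id: str
    n_mqtl: int
    delta_adj_r2: float


def gxe_scan(m_values, genotypes: GenotypeMatrix, theta, covariates,
             main_fit) -> pd.DataFrame:
    """Gene-by-season interaction scan for one CpG.

    Model: ``M ~ covs + f(theta) + G + G * f(theta)`` where f is sin or
    cos, whichever was the more significant Fourier term in the main
    seasonal fit for this CpG (ties fall to sin). The interaction
    coefficient is t-tested per SNP; q-values are BH over all SNPs.
    """
    sin_p = getattr(main_fit, "sin_p", np.nan)
    cos_p = getattr(main_fit, "cos_p", np.nan)
    term = "sin" if (np.isnan(cos_p) or sin_p <= cos_p) else "cos"
    theta = np.asarray(theta, dtype=float)
    f = np.sin(theta) if term == "sin" else np.cos(theta)
    y = np.asarray(m_values, dtype=float)
    n = len(y)
    Xbase = np.hstack([_design_with_intercept(covariates, n), f[:, None]])
    rows = []
    for snp in genotypes.dosages.columns:
        g = genotypes.dosages[snp].to_numpy(dtype=float)
        X = np.hstack([Xbase, g[:, None], (g * f)[:, None]])
        k = X.shape[1]
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sigma2 = float(resid @ resid) / (n - k)
        XtX_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * XtX_inv[-1, -1])
        t = coef[-1] / se
        p = 2.0 * stats.t.sf(abs(t), n - k)
        rows.append((snp, term, float(coef[-1]), float(p)))
    out = pd.DataFrame(rows, columns=["snp_id", "term", "coef", "p"])
    out["q"] = fdr_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def soc_genotype_association(genotypes: GenotypeMatrix, metadata,
                             mode: str = "regression",
                             season_windows: dict | None = None,
                             n_dependent: int | None = None) -> pd.DataFrame:
    """Test SNPs for association with season of conception.

    A guard against genetic confounding: if SNP dosages track conception
    season, seasonal methylation signals at their target CpGs could be
    genetic rather than environmental.

    ``regression`` mode regresses dosage on sin/cos of the conception
    angle and reports the joint F-test p per SNP. ``dichotomised`` mode
    requires ``season_windows`` — ``{"rainy": (start_doy, end_doy),
    "dry": (start_doy, end_doy)}`` day-of-year ranges — and performs a
    2x2 allele-count chi-square between the two season groups.

    Returns per-SNP p with BH q-values and a Bonferroni threshold
    (0.05 / ``n_dependent``, defaulting to the number of SNPs).
    """
    meta = getattr(metadata, "frame", metadata)
    theta = meta["theta"].to_numpy(dtype=float) if "theta" in meta else np.array(
        [conception_theta(d) for d in meta["conception_date"]])
    rows = []
    if mode == "regression":
        n = len(theta)
        X = np.column_stack([np.ones(n), np.sin(theta), np.cos(theta)])
        for snp in genotypes.dosages.columns:
            g = genotypes.dosages[snp].to_numpy(dtype=float)
            coef, _, _, _ = np.linalg.lstsq(X, g, rcond=None)
            rss = float(np.sum((g - X @ coef) ** 2))
            tss = float(np.sum((g - g.mean()) ** 2))
            df1, df2 = 2, n - 3
            fstat = ((tss - rss) / df1) / (rss / df2) if rss > 0 else np.inf
            p = float(stats.f.sf(fstat, df1, df2))
            rows.append((snp, p))
    elif mode == "dichotomised":
        if not season_windows or set(season_windows) != {"rainy", "dry"}:
            raise ValueError("dichotomised mode needs rainy and dry season windows")
        doy = theta / (2.0 * np.pi) * 365.0
        groups = {}
        for name, (lo, hi) in season_windows.items():
            if lo <= hi:
                groups[name] = (doy >= lo) & (doy <= hi)
            else:  # window wraps the new year
                groups[name] = (doy >= lo) | (doy <= hi)
            if groups[name].sum() == 0:
                raise ValueError(f"season group {name!r} is empty")
        for snp in genotypes.dosages.columns:
            g = genotypes.dosages[snp].to_numpy(dtype=float)
            table = []
            for name in ("rainy", "dry"):
                sel = g[groups[name]]
                alt = float(sel.sum())
                table.append([alt, 2.0 * len(sel) - alt])
            chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
            rows.append((snp, float(p)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = pd.DataFrame(rows, columns=["snp_id", "p"])
    out["q"] = fdr_adjust(out["p"].to_numpy()) if len(out) else []
    m = n_dependent if n_dependent else max(len(out), 1)
    out.attrs["bonferroni_threshold"] = 0.05 / m
    return out
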