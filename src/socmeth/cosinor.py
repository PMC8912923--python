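"""Per-CpG Fourier (cosinor) regression and seasonal-effect summaries.

The seasonal model for CpG j and individual i is

    M_ij = a_0j + sum_k a_k x_ik + sum_r [b_rj sin(r theta_i) + g_rj cos(r theta_i)] + e_ij

where M is the log2-odds methylation value, theta_i encodes the date of
conception as an angle over the year, x_ik are adjustment covariates, and
r indexes Fourier pairs (default one pair, giving a sinusoid whose maximum
and minimum are half a year apart). Seasonal significance is a likelihood
ratio test of the full model against the covariate-only model (chi-square,
2 df per pair); the seasonal amplitude is the peak-to-nadir distance of
the fitted curve on the back-transformed percent-methylation scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import beta_to_m, m_to_beta, outlier_bounds

#: Number of days in the daily prediction grid used for amplitude/phase.
GRID_DAYS = 365


@dataclass
class LinearFit:
    """A fitted ordinary-least-squares model, kept for LRT bookkeeping."""

    coef: np.ndarray
    rss: float
    n: int
    rank: int
    columns: list
    sample_index: np.ndarray | None = None

    @property
    def loglik(self) -> float:
        """Gaussian log-likelihood at the MLE variance (RSS / n)."""
        n = self.n
        return -0.5 * n * (np.log(2.0 * np.pi * self.rss / n) + 1.0)


@dataclass
class CosinorFit:
    """Per-CpG cosinor fit summary.

    ``beta1``/``gamma1`` are the sin/cos coefficients of the first Fourier
    pair on the M-value scale. ``amplitude_pct`` is the peak-to-nadir
    distance of the fitted seasonal curve in percent methylation, evaluated
    at the covariate reference point. ``peak_day``/``nadir_day`` are days of
    year (0 = 1 January); NaN when the seasonal coefficients are all zero.
    """

    cpg_id: str
    intercept: float
    beta1: float
    gamma1: float
    covariate_coefs: dict = field(default_factory=dict)
    sin_p: float = np.nan
    cos_p: float = np.nan
    lrt_stat: float = np.nan
    p_value: float = np.nan
    q_value: float = np.nan
    amplitude_pct: float = np.nan
    peak_day: float = np.nan
    nadir_day: float = np.nan
    n_used: int = 0
    n_outliers: int = 0


def _design(theta: np.ndarray, covariates, n_pairs: int = 1):
    """Build the full design matrix [1 | covariates | sin/cos pairs]."""
    theta = np.asarray(theta, dtype=float)
    n = theta.shape[0]
    cols = ["intercept"]
    blocks = [np.ones((n, 1))]
    if covariates is not None:
        C = pd.DataFrame(covariates)
        blocks.append(np.asarray(C, dtype=float))
        cols.extend(str(c) for c in C.columns)
    for r in range(1, n_pairs + 1):
        blocks.append(np.column_stack([np.sin(r * theta), np.cos(r * theta)]))
        suffix = "" if r == 1 else str(r)
        cols.extend([f"sin{suffix}", f"cos{suffix}"])
    return np.hstack(blocks), cols


def _check_rank(X: np.ndarray, cols) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by rank-revealing QR pivots
        _, R, piv = _qr_pivot(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [cols[piv[i]] for i in range(len(cols)) if i >= rank or diag[i] < tol]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _qr_pivot(X):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def _ols(X: np.ndarray, y: np.ndarray, cols, sample_index=None) -> LinearFit:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return LinearFit(coef=coef, rss=float(resid @ resid), n=len(y), rank=rank,
                     columns=list(cols), sample_index=sample_index)


def lrt_pvalue(full_fit: LinearFit, reduced_fit: LinearFit, df: int = 2):
    """Likelihood-ratio test of a full vs a nested covariate-only model.

    The statistic is ``2 * (loglik_full - loglik_reduced)`` under the
    Gaussian likelihood (equivalently ``n * log(RSS_reduced / RSS_full)``)
    and is referred to a chi-square distribution with ``df`` degrees of
    freedom (2 per Fourier pair).

    Both fits must have been computed on the identical sample set.
    """
    if full_fit.n != reduced_fit.n:
        raise ValueError("full and reduced models were fit on different sample sets")
    if (full_fit.sample_index is not None and reduced_fit.sample_index is not None
            and not np.array_equal(full_fit.sample_index, reduced_fit.sample_index)):
        raise ValueError("full and reduced models were fit on different sample sets")
    stat = 2.0 * (full_fit.loglik - reduced_fit.loglik)
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df))


def fdr_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Parameters
    ----------
    p_values : array-like of p in [0, 1]
    m : int, optional
        Number of independent tests assumed. Defaults to ``len(p_values)``;
        a larger value reproduces the convention of adjusting against a
        fixed background of tests (e.g. the full array background) when
        only a subset of p-values is supplied.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    if m is None:
        m = k
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(k)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def amplitude_phase(intercept: float, beta1: float, gamma1: float,
                    covariate_offset: float = 0.0, grid_days: int = GRID_DAYS):
    """Seasonal amplitude (percent methylation) and peak/nadir days.

    The fitted M-value curve is evaluated on a daily grid over the year at
    the covariate reference point (``covariate_offset`` is the covariate
    contribution at that reference), back-transformed to the beta scale,
    and summarised as (max - min) * 100 with the argmax/argmin days.

    The closed form for the single-pair model — M-scale acrophase at
    ``atan2(beta1, gamma1)`` and M-scale peak-to-nadir ``2*sqrt(b^2+g^2)``
    — agrees with the grid to within one grid step and is used as a
    cross-check in the test-suite; the grid is authoritative because it
    extends unchanged to multi-pair models.

    Returns ``(amplitude_pct, peak_day, nadir_day)``; days are NaN when
    both seasonal coefficients are zero.
    """
    if beta1 == 0.0 and gamma1 == 0.0:
        return 0.0, np.nan, np.nan
    days = np.arange(grid_days)
    theta = 2.0 * np.pi * days / grid_days
    m_curve = intercept + covariate_offset + beta1 * np.sin(theta) + gamma1 * np.cos(theta)
    b_curve = m_to_beta(m_curve)
    amp = float((b_curve.max() - b_curve.min()) * 100.0)
    return amp, float(days[np.argmax(b_curve)]), float(days[np.argmin(b_curve)])


def fit_cosinor(m_values, theta, covariates=None, cpg_id: str = "",
                n_pairs: int = 1) -> CosinorFit:
    """Fit the cosinor model to one CpG by ordinary least squares.

    Parameters
    ----------
    m_values : array-like
        M-values for one CpG; NaNs are dropped (together with the matching
        rows of ``theta`` and ``covariates``).
    theta : array-like
        Conception-date angles in [0, 2*pi).
    covariates : DataFrame or array, optional
        Numeric adjustment covariates, one row per sample (no intercept).
    n_pairs : int
        Number of Fourier pairs (default 1, a single sinusoid).

    Raises
    ------
    ValueError
        If the design is rank deficient (the error names the collinear
        columns, e.g. when theta is constant) or too few samples remain.
    """
    y = np.asarray(m_values, dtype=float)
    theta = np.asarray(theta, dtype=float)
    keep = np.isfinite(y)
    n_out = int((~keep).sum())
    y = y[keep]
    theta_k = theta[keep]
    cov_k = None
    if covariates is not None:
        cov_k = pd.DataFrame(covariates).iloc[keep]
    X, cols = _design(theta_k, cov_k, n_pairs)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("too few samples for the requested design")
    _check_rank(X, cols)
    idx = np.flatnonzero(keep)
    full = _ols(X, y, cols, idx)
    X_red = X[:, : X.shape[1] - 2 * n_pairs]
    reduced = _ols(X_red, y, cols[: len(cols) - 2 * n_pairs], idx)
    stat, p = lrt_pvalue(full, reduced, df=2 * n_pairs)

    # marginal t-tests for each Fourier term (used for GxE term selection)
    n, k = X.shape
    sigma2 = full.rss / (n - k)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    tvals = full.coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), n - k)
    sin_i, cos_i = k - 2 * n_pairs, k - 2 * n_pairs + 1

    cov_names = cols[1: k - 2 * n_pairs]
    cov_coefs = dict(zip(cov_names, full.coef[1: k - 2 * n_pairs]))
    offset = _reference_offset(cov_k, np.array(list(cov_coefs.values())))
    amp, peak, nadir = amplitude_phase(full.coef[0], full.coef[sin_i],
                                       full.coef[cos_i], offset)
    return CosinorFit(
        cpg_id=cpg_id, intercept=float(full.coef[0]),
        beta1=float(full.coef[sin_i]), gamma1=float(full.coef[cos_i]),
        covariate_coefs=cov_coefs, sin_p=float(pvals[sin_i]),
        cos_p=float(pvals[cos_i]), lrt_stat=stat, p_value=p,
        amplitude_pct=amp, peak_day=peak, nadir_day=nadir,
        n_used=len(y), n_outliers=n_out,
    )


def _reference_offset(covariates, coefs: np.ndarray) -> float:
    """Covariate contribution at the reference point.

    Reference is the mean for continuous covariates and the modal value
    for binary (two-level indicator) columns, so amplitudes are reported
    for a 'typical' individual rather than an impossible fractional one.
    """
    if covariates is None or len(coefs) == 0:
        return 0.0
    C = np.asarray(pd.DataFrame(covariates), dtype=float)
    ref = np.empty(C.shape[1])
    for j in range(C.shape[1]):
        col = C[:, j]
        uniq = np.unique(col)
        if len(uniq) <= 2:
            vals, counts = np.unique(col, return_counts=True)
            ref[j] = vals[np.argmax(counts)]
        else:
            ref[j] = col.mean()
    return float(ref @ coefs)


def run_ewas(methylation, metadata, covariates=None, n_pairs: int = 1,
             fdr_m: int | None = None, mask_outliers: bool = True) -> pd.DataFrame:
    """Cosinor EWAS over every CpG in a methylation matrix.

    Per CpG: mask beta-scale outliers (3x IQR beyond the quartiles), fit
    the full and covariate-only models on the surviving samples, record
    the LRT p-value, and summarise amplitude and phase. q-values are BH
    over all analysed CpGs (or against ``fdr_m`` assumed tests).

    Parameters
    ----------
    methylation : DataFrame or MethylationMatrix
        Samples x CpGs beta values. (A ``MethylationMatrix`` is accepted
        and its ``betas`` frame used.)
    metadata : DataFrame or SampleMetadata
        Must carry a ``theta`` column aligned to the methylation rows.
    covariates : DataFrame, optional
        Numeric design columns, same index as the methylation rows.

    Returns
    -------
    DataFrame indexed by CpG id with columns
    ``intercept, beta1, gamma1, sin_p, cos_p, lrt_stat, p_value, q_value,
    amplitude_pct, peak_day, nadir_day, n_used, n_outliers``. Run
    metadata (covariate list, sample count, mean outliers removed) is in
    ``.attrs``.
    """
    betas = getattr(methylation, "betas", methylation)
    meta = getattr(metadata, "frame", metadata)
    if not betas.index.equals(meta.index):
        missing = betas.index.symmetric_difference(meta.index).tolist()
        raise ValueError(f"sample IDs of methylation and metadata differ: {missing[:10]}")
    if covariates is not None and not betas.index.equals(pd.DataFrame(covariates).index):
        missing = betas.index.symmetric_difference(pd.DataFrame(covariates).index).tolist()
        raise ValueError(f"sample IDs of methylation and covariates differ: {missing[:10]}")

    theta = np.asarray(meta["theta"], dtype=float)
    B = np.asarray(betas, dtype=float)
    n, p = B.shape

    if mask_outliers:
        lo, hi = outlier_bounds(B)
        out = np.isfinite(B) & ((B < lo) | (B > hi))
        B = np.where(out, np.nan, B)
    M = np.where(np.isfinite(B), beta_to_m(np.where(np.isfinite(B), B, 0.5)), np.nan)

    X, cols = _design(theta, covariates, n_pairs)
    _check_rank(X, cols)
    k = X.shape[1]
    n_fourier = 2 * n_pairs
    X_red = X[:, : k - n_fourier]

    coefs = np.empty((p, k))
    rss_full = np.empty(p)
    rss_red = np.empty(p)
    n_used = np.empty(p, dtype=int)
    n_out = (~np.isfinite(M)).sum(axis=0)

    clean = n_out == 0
    if clean.any():
        Yc = M[:, clean]
        pinv = np.linalg.pinv(X)
        Cf = pinv @ Yc
        Rf = Yc - X @ Cf
        pinv_r = np.linalg.pinv(X_red)
        Cr = pinv_r @ Yc
        Rr = Yc - X_red @ Cr
        coefs[clean] = Cf.T
        rss_full[clean] = np.einsum("ij,ij->j", Rf, Rf)
        rss_red[clean] = np.einsum("ij,ij->j", Rr, Rr)
        n_used[clean] = n

    for j in np.flatnonzero(~clean):
        keep = np.isfinite(M[:, j])
        y = M[keep, j]
        Xj, Xjr = X[keep], X_red[keep]
        cj, _, _, _ = np.linalg.lstsq(Xj, y, rcond=None)
        cr, _, _, _ = np.linalg.lstsq(Xjr, y, rcond=None)
        coefs[j] = cj
        rss_full[j] = float(np.sum((y - Xj @ cj) ** 2))
        rss_red[j] = float(np.sum((y - Xjr @ cr) ** 2))
        n_used[j] = int(keep.sum())

    with np.errstate(divide="ignore", invalid="ignore"):
        lrt = n_used * np.log(rss_red / rss_full)
    lrt = np.clip(lrt, 0.0, None)
    pvals = stats.chi2.sf(lrt, n_fourier)
    qvals = fdr_adjust(pvals, m=fdr_m)

    # marginal sin/cos p-values (clean-path approximation exact for OLS on
    # the full sample; masked CpGs use their own design below)
    sin_i, cos_i = k - n_fourier, k - n_fourier + 1
    sin_p = np.full(p, np.nan)
    cos_p = np.full(p, np.nan)
    if clean.any():
        XtX_inv_diag = np.diag(np.linalg.inv(X.T @ X))
        dof = n - k
        sigma2 = rss_full[clean] / dof
        se_sin = np.sqrt(sigma2 * XtX_inv_diag[sin_i])
        se_cos = np.sqrt(sigma2 * XtX_inv_diag[cos_i])
        sin_p[clean] = 2 * stats.t.sf(np.abs(coefs[clean, sin_i] / se_sin), dof)
        cos_p[clean] = 2 * stats.t.sf(np.abs(coefs[clean, cos_i] / se_cos), dof)
    for j in np.flatnonzero(~clean):
        keep = np.isfinite(M[:, j])
        Xj = X[keep]
        dof = n_used[j] - k
        XtX_inv_diag = np.diag(np.linalg.inv(Xj.T @ Xj))
        sigma2 = rss_full[j] / dof
        sin_p[j] = 2 * stats.t.sf(abs(coefs[j, sin_i] / np.sqrt(sigma2 * XtX_inv_diag[sin_i])), dof)
        cos_p[j] = 2 * stats.t.sf(abs(coefs[j, cos_i] / np.sqrt(sigma2 * XtX_inv_diag[cos_i])), dof)

    # amplitude/phase on the daily grid, vectorised across CpGs
    cov_cols = cols[1: k - n_fourier]
    offsets = np.zeros(p)
    if covariates is not None and len(cov_cols):
        C = np.asarray(pd.DataFrame(covariates), dtype=float)
        ref = np.empty(C.shape[1])
        for j in range(C.shape[1]):
            col = C[:, j]
            if len(np.unique(col)) <= 2:
                vals, counts = np.unique(col, return_counts=True)
                ref[j] = vals[np.argmax(counts)]
            else:
                ref[j] = col.mean()
        offsets = coefs[:, 1: k - n_fourier] @ ref

    days = np.arange(GRID_DAYS)
    tgrid = 2.0 * np.pi * days / GRID_DAYS
    curve = coefs[:, [0]] + offsets[:, None]
    for r in range(1, n_pairs + 1):
        si = k - n_fourier + 2 * (r - 1)
        curve = curve + coefs[:, [si]] * np.sin(r * tgrid)[None, :] \
                      + coefs[:, [si + 1]] * np.cos(r * tgrid)[None, :]
    bcurve = m_to_beta(curve)
    amp = (bcurve.max(axis=1) - bcurve.min(axis=1)) * 100.0
    peak = days[np.argmax(bcurve, axis=1)].astype(float)
    nadir = days[np.argmin(bcurve, axis=1)].astype(float)
    flat = (coefs[:, sin_i] == 0) & (coefs[:, cos_i] == 0)
    amp[flat] = 0.0
    peak[flat] = np.nan
    nadir[flat] = np.nan

    table = pd.DataFrame({
        "intercept": coefs[:, 0],
        "beta1": coefs[:, sin_i],
        "gamma1": coefs[:, cos_i],
        "sin_p": sin_p,
        "cos_p": cos_p,
        "lrt_stat": lrt,
        "p_value": pvals,
        "q_value": qvals,
        "amplitude_pct": amp,
        "peak_day": peak,
        "nadir_day": nadir,
        "n_used": n_used,
        "n_outliers": n_out,
    }, index=pd.Index(betas.columns, name="cpg_id"))
    table.attrs["covariates"] = list(cov_cols)
    table.attrs["n_samples"] = n
    table.attrs["n_pairs"] = n_pairs
    table.attrs["mean_outliers_per_cpg"] = float(n_out.mean())
    table.attrs["total_outliers"] = int(n_out.sum())
    return table


def inflation_lambda(p_values) -> float:
    """Genomic inflation factor of a p-value vector.

    p-values are converted to 1-df chi-square quantiles; lambda is their
    median divided by the null median 0.4549364 (the median of a 1-df
    chi-square). Under a well-calibrated null, lambda is approximately 1.
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) < 100:
        raise ValueError("need at least 100 p-values for a stable lambda")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, 1))
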