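"""Transformations and covariate construction applied before model fitting.

Methylation arrays report beta values (fraction methylated, in [0, 1]).
Statistical modelling is done on M-values, the log2 odds of methylation,
which are closer to homoscedastic. This module provides the beta/M
transforms, the per-CpG outlier rule, conception-date handling for the
cyclical predictor, principal-component covariates, and the optional
covariate pre-adjustment used in sensitivity analyses.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

#: Beta values are clamped into [BETA_EPS, 1 - BETA_EPS] before the logit so
#: that boundary values do not produce infinite M-values.
BETA_EPS = 1e-6

#: Average gestation length (days) used to derive conception date from birth
#: date when gestational age is not directly measured.
GESTATION_DAYS = 280


def beta_to_m(beta, eps: float = BETA_EPS):
    """Convert methylation beta values to M-values (log2 odds).

    Parameters
    ----------
    beta : array-like or scalar
        Methylation fractions in [0, 1]. Values at exactly 0 or 1 are
        clamped to ``eps`` / ``1 - eps``.
    eps : float
        Clamping distance from the boundary.

    Returns
    -------
    M-values, ``log2(beta / (1 - beta))``, same shape as the input.
    NaNs are propagated.

    Raises
    ------
    ValueError
        If any finite value lies outside [0, 1].
    """
    arr = np.asarray(beta, dtype=float)
    finite = np.isfinite(arr)
    if np.any((arr[finite] < 0) | (arr[finite] > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    clamped = np.clip(arr, eps, 1.0 - eps)
    out = np.log2(clamped / (1.0 - clamped))
    if np.isscalar(beta):
        return float(out)
    return out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: ``2**M / (1 + 2**M)``."""
    arr = np.asarray(m, dtype=float)
    # computed via expit-style stable form to avoid overflow for large |M|
    out = np.empty_like(arr)
    pos = arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-arr[pos]))
    out[~pos] = np.exp2(arr[~pos]) / (1.0 + np.exp2(arr[~pos]))
    if np.isscalar(m):
        return float(out)
    return out


def remove_outliers(values, factor: float = 3.0):
    """Mask extreme methylation values using the 3x-IQR rule.

    Values more than ``factor`` times the inter-quartile range beyond the
    25th or 75th percentile are replaced by NaN. Quartiles use linear
    (type-7) interpolation and are computed once on the input (single
    pass; masking does not trigger re-computation).

    Parameters
    ----------
    values : array-like
        Beta values for one CpG across samples; NaNs allowed.
    factor : float
        IQR multiplier (default 3).

    Returns
    -------
    (masked, n_removed) : (ndarray, int)

    Raises
    ------
    ValueError
        If fewer than 4 non-missing values are supplied.
    """
    arr = np.asarray(values, dtype=float).copy()
    ok = np.isfinite(arr)
    if ok.sum() == 0:
        raise ValueError("all values are missing")
    if ok.sum() < 4:
        raise ValueError("need at least 4 non-missing values for the IQR rule")
    q25, q75 = np.nanquantile(arr, [0.25, 0.75])
    iqr = q75 - q25
    lo, hi = q25 - factor * iqr, q75 + factor * iqr
    out_mask = ok & ((arr < lo) | (arr > hi))
    arr[out_mask] = np.nan
    return arr, int(out_mask.sum())


def outlier_bounds(matrix: np.ndarray, factor: float = 3.0):
    """Vectorised per-column (lo, hi) bounds of the 3x-IQR rule.

    ``matrix`` is samples x CpGs. Returns two arrays of length n_cpgs.
    """
    q25 = np.nanquantile(matrix, 0.25, axis=0)
    q75 = np.nanquantile(matrix, 0.75, axis=0)
    iqr = q75 - q25
    return q25 - factor * iqr, q75 + factor * iqr


def compute_pcs(m_matrix, k: int) -> np.ndarray:
    """First ``k`` principal-component scores of an M-value matrix.

    Unsupervised PCA of the samples x CpGs matrix, columns centred.
    Scores are variance-ordered and mutually orthogonal. Sign convention:
    the loading with the largest magnitude on each component is positive,
    which makes the scores reproducible across equivalent decompositions.

    Raises
    ------
    ValueError
        If ``k`` is not in [1, min(n_samples, n_cpgs)].
    """
    X = np.asarray(m_matrix, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(n_samples, n_cpgs)={min(X.shape)}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    load = pca.components_
    for i in range(k):
        j = int(np.argmax(np.abs(load[i])))
        if load[i, j] < 0:
            scores[:, i] = -scores[:, i]
            load[i] = -load[i]
    return scores


def conception_theta(date: dt.date) -> float:
    """Map a conception date to an angle in [0, 2*pi).

    1 January maps to 0 and 31 December to just under 2*pi; the fraction
    of the year elapsed is computed against the actual length of that
    calendar year (365 or 366 days).
    """
    year_start = dt.date(date.year, 1, 1)
    days_elapsed = (date - year_start).days
    year_len = (dt.date(date.year + 1, 1, 1) - year_start).days
    return 2.0 * np.pi * days_elapsed / year_len


def conception_from_birth(birth_date: dt.date,
                          gestation_days: int = GESTATION_DAYS) -> dt.date:
    """Estimate conception date as birth date minus the average gestation.

    The default of 280 days is the average gestational length for the
    study population; pass ``gestation_days=0`` for an identity mapping.
    """
    return birth_date - dt.timedelta(days=gestation_days)


def preadjust_covariate(m_matrix: pd.DataFrame, covariate) -> pd.DataFrame:
    """Regress a single covariate out of every CpG column.

    Used in sensitivity analyses: the covariate effect is removed from
    the M-value matrix before the main seasonal regression. Per CpG, a
    simple regression on the covariate (with intercept) is fitted and
    the residuals are returned with the CpG mean restored.

    Parameters
    ----------
    m_matrix : DataFrame
        Samples x CpGs M-values.
    covariate : array-like
        One value per sample; must vary.

    Raises
    ------
    ValueError
        If the covariate is constant.
    """
    x = np.asarray(covariate, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant across samples")
    Y = np.asarray(m_matrix, dtype=float)
    xc = x - x.mean()
    slope = xc @ Y / (xc @ xc)
    resid = Y - np.outer(xc, slope)
    # after removing the centred covariate the column means are untouched,
    # so `resid` already preserves per-CpG means
    if isinstance(m_matrix, pd.DataFrame):
        return pd.DataFrame(resid, index=m_matrix.index, columns=m_matrix.columns)
    return resid


def build_covariates(metadata: pd.DataFrame,
                     columns=("sex", "age", "batch", "intervention"),
                     pcs: np.ndarray | None = None) -> pd.DataFrame:
    """Assemble a numeric covariate design from sample metadata.

    Categorical columns (``batch``, ``intervention``, and any
    non-numeric column) are expanded to 0/1 indicators with the first
    level dropped; numeric columns pass through. PC scores, if given,
    are appended as ``PC1..PCk``. The intercept is *not* included — the
    model-fitting code adds it.
    """
    parts = []
    for col in columns:
        if col not in metadata.columns:
            continue
        s = metadata[col]
        if s.dtype.kind in "biufc" and s.nunique() > 2:
            parts.append(s.astype(float).rename(col))
        elif s.dtype.kind in "biufc":
            parts.append(s.astype(float).rename(col))
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
    out = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=metadata.index)
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        for i in range(pcs.shape[1]):
            out[f"PC{i + 1}"] = pcs[:, i]
    return out
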