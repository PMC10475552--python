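"""Shared statistical kernels.

Summary-statistic Welch tests, 2x2 chi-square, GLM contrasts and partial
Pearson correlation, used by the motion-QC, static-FC, dynamic-FC and
temporal-metrics stages as well as the demographics (``table1``) command.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "SummaryGroup",
    "welch_t_from_summary",
    "chi_square_2x2",
    "glm_contrast",
    "glm_contrast_many",
    "partial_pearson",
]


@dataclass(frozen=True)
class SummaryGroup:
    """Mean +/- SD summary of one group, as printed in demographic tables."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got n={self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be nonnegative, got {self.sd}")


def welch_t_from_summary(a: SummaryGroup, b: SummaryGroup):
    """Unequal-variance (Welch) two-sample t-test from group summaries.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom and a
    two-sided p-value.  The Welch form is the default because it reproduces
    published head-motion comparisons computed from group mean/SD summaries.
    """
    if a.sd == 0 and b.sd == 0:
        raise ValueError("both group SDs are zero; t statistic undefined")
    t, p = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False
    )
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(t), float(df), float(p)


def pooled_t_from_summary(a: SummaryGroup, b: SummaryGroup):
    """Equal-variance (pooled) two-sample t from group summaries."""
    if a.sd == 0 and b.sd == 0:
        raise ValueError("both group SDs are zero; t statistic undefined")
    t, p = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return float(t), float(a.n + b.n - 2), float(p)


def chi_square_2x2(table, yates: bool = False):
    """Pearson chi-square test on a 2x2 contingency table.

    Parameters
    ----------
    table : array-like, shape (2, 2)
        Nonnegative integer counts.  All row and column margins must be
        positive for the expected counts to be defined.
    yates : bool
        Apply the continuity correction.  Off by default: the uncorrected
        statistic is what sex-distribution comparisons in demographic tables
        conventionally print.

    Returns ``(chi2, df, p)`` with df = 1.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all table margins must be positive")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=yates)
    return float(chi2), int(df), float(p)


def glm_contrast(y, design, contrast_index: int):
    """OLS fit of ``y`` on ``design``; t-test on one coefficient.

    ``design`` must already contain an intercept column if one is wanted.
    Returns ``(estimate, t, p)`` for the column at ``contrast_index``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("design must be 2-D with one row per observation")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than design columns")
    res = sm.OLS(y, X).fit()
    return (
        float(res.params[contrast_index]),
        float(res.tvalues[contrast_index]),
        float(res.pvalues[contrast_index]),
    )


def glm_contrast_many(Y, design, contrast_index: int):
    """Vectorised OLS contrast over many response columns sharing one design.

    Used for edge-wise connectivity contrasts where the same
    intercept+group+age+sex design is fitted to hundreds of edges.

    Parameters
    ----------
    Y : ndarray, shape (n_obs, n_responses)
    design : ndarray, shape (n_obs, n_cols)
    contrast_index : int
        Column of ``design`` whose coefficient is tested.

    Returns
    -------
    beta, t, p : ndarrays of shape (n_responses,)
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(design, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    if n <= k:
        raise ValueError("need more observations than design columns")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta_all = XtX_inv @ (X.T @ Y)  # (k, E)
    resid = Y - X @ beta_all
    dof = n - k
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[contrast_index, contrast_index], 0.0))
    beta = beta_all[contrast_index]
    # a perfectly fitted (e.g. constant) response has no sampling noise left;
    # report t = 0 instead of 0/0 roundoff garbage
    rms = np.sqrt(np.einsum("ij,ij->j", Y, Y) / n)
    floor = np.sqrt(np.finfo(float).eps) * (rms + 1.0) * 1e-2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > floor, beta / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    return beta, t, p


def partial_pearson(x, y, covariates=None):
    """Pearson correlation of ``x`` and ``y`` after removing covariates.

    Both variables are residualised on ``[intercept, covariates]`` by OLS and
    the residuals are correlated; with ``c`` covariates the p-value comes from
    ``t = r * sqrt((n - 2 - c) / (1 - r^2))`` on ``n - 2 - c`` degrees of
    freedom.  With no covariates this reduces to the plain Pearson test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if covariates is None or (np.asarray(covariates).size == 0):
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    c = C.shape[1]
    if n <= c + 3:
        raise ValueError(f"need n > n_covariates + 3, got n={n}, c={c}")
    Z = np.column_stack([np.ones(n), C])
    coef_x, *_ = np.linalg.lstsq(Z, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
    rx = x - Z @ coef_x
    ry = y - Z @ coef_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("constant residuals; partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - 2 - c
    r_clamped = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clamped * np.sqrt(dof / (1.0 - r_clamped**2))
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return r, p
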