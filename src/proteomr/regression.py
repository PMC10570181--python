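"""Covariate design matrices and vectorised ordinary least squares.

All adjusted analyses in the pipeline share the same covariate vocabulary
(age, age-squared, sex, study area, fasting time, ambient temperature,
assay plate, case-subcohort ascertainment, national principal components).
This module turns a cohort table into a numeric design matrix and provides
a multi-response OLS fit that is reused by the observational scan, the
two-stage least squares stages and the stratified non-linear MR numerators.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("proteomr")

# Adjustment sets used by the three regression contexts.  The observational
# model adjusts for plate; the instrument (stage-1) model swaps plate for the
# first 12 national principal components; the stage-2 model adds plate back
# and drops the principal components.
OBS_COVARIATES = ("age", "age2", "sex", "area", "fasting_time",
                  "ambient_temp", "plate", "ascertainment")
STAGE1_COVARIATES = ("age", "age2", "sex", "area", "fasting_time",
                     "ambient_temp", "ascertainment", "pcs")
STAGE2_COVARIATES = ("age", "age2", "sex", "area", "fasting_time",
                     "ambient_temp", "ascertainment", "plate")

N_PCS = 12
_CATEGORICAL = {"area", "plate"}


def design_matrix(cohort: pd.DataFrame, covariates=OBS_COVARIATES):
    """Build an intercept-first numeric design matrix from cohort columns.

    ``age2`` is the square of centered age (centering leaves estimates of
    other coefficients invariant but improves conditioning). ``area`` and
    ``plate`` expand into first-level-reference dummy sets; ``pcs`` expands
    into the 12 principal-component columns. Collinear columns are dropped
    with a log message.

    Returns
    -------
    (X, names) : ndarray of shape (n, k) with the intercept first, and the
    column names.
    """
    n = len(cohort)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    age_c = None
    if "age" in covariates or "age2" in covariates:
        age_c = cohort["age"].to_numpy(float) - cohort["age"].mean()
    for cov in covariates:
        if cov == "age":
            cols.append(age_c)
            names.append("age")
        elif cov == "age2":
            cols.append(age_c ** 2)
            names.append("age2")
        elif cov == "pcs":
            for i in range(1, N_PCS + 1):
                cols.append(cohort[f"pc{i}"].to_numpy(float))
                names.append(f"pc{i}")
        elif cov in _CATEGORICAL:
            dummies = pd.get_dummies(cohort[cov], prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(float))
                names.append(str(c))
        else:
            cols.append(cohort[cov].to_numpy(float))
            names.append(cov)
    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in covariate design matrix")
    return drop_collinear(X, names)


def drop_collinear(X: np.ndarray, names: list[str], tol: float = 1e-9):
    """Greedily drop columns that add no rank (keeping the intercept)."""
    keep = [0]
    for j in range(1, X.shape[1]):
        cand = X[:, keep + [j]]
        # rank via economical QR diagonal
        r = np.abs(np.diag(np.linalg.qr(cand, mode="r")))
        if r.min() > tol * max(r.max(), 1.0):
            keep.append(j)
        else:
            logger.info("dropping collinear design column %s", names[j])
    if len(keep) < X.shape[1]:
        X = X[:, keep]
        names = [names[j] for j in keep]
    return X, list(names)


def ols_multi(X: np.ndarray, Y: np.ndarray):
    """Multi-response OLS: regress each column of Y on the same X.

    Returns (beta, se, resid, df) with beta and se of shape (k, p).
    Requires X of full column rank (use :func:`design_matrix`, which
    guarantees it) and n > k.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n={n} observations <= k={k} parameters")
    XtXi = np.linalg.inv(X.T @ X)
    beta = XtXi @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - k
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(np.outer(np.diag(XtXi), sigma2))
    return beta, se, resid, df


def slope_on(X: np.ndarray, x: np.ndarray, Y: np.ndarray):
    """Coefficient (and SE, t-p) of predictor ``x`` added to design ``X``.

    Convenience wrapper used throughout: returns per-response slope, its
    standard error, the two-sided t-test p-value and the residual df.
    """
    from scipy import stats

    Xf = np.column_stack([X, x])
    beta, se, _, df = ols_multi(Xf, Y)
    b, s = beta[-1], se[-1]
    t = b / s
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return b, s, p, df


def incremental_r2(X: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    """Increase in R^2 for y when predictor x is added to design X."""
    y = np.asarray(y, float)
    sst = np.sum((y - y.mean()) ** 2)
    _, _, r0, _ = ols_multi(X, y)
    _, _, r1, _ = ols_multi(np.column_stack([X, x]), y)
    return float((np.sum(r0 ** 2) - np.sum(r1 ** 2)) / sst)
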