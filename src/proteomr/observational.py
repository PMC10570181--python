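"""Observational per-protein associations of BMI with standardized NPX
levels, and the BMI-quintile shape analysis.

Protein values are standardized by dividing by their sample SD (division
only; means are not shifted), BMI enters in SD units, and each protein is
regressed on BMI with the full observational covariate adjustment (age,
age squared, sex, study area, fasting time, ambient temperature, plate and
case-subcohort ascertainment).  Multiplicity is controlled by BH FDR with a
Bonferroni flag alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from proteomr.multiplicity import bh_qvalues, bonferroni_flags
from proteomr.regression import OBS_COVARIATES, design_matrix, ols_multi
from proteomr.synthdata import ProteinPanel

logger = logging.getLogger("proteomr")

__all__ = ["standardize_proteins", "fit_protein_associations",
           "quintile_profile", "QuintileProfile"]


def standardize_proteins(panel) -> pd.DataFrame:
    """Divide each protein by its sample SD (ddof=1); means are not shifted.

    Zero-variance proteins are excluded with a warning. Accepts a
    :class:`~proteomr.synthdata.ProteinPanel` or a bare NPX DataFrame.
    """
    npx = panel.npx if isinstance(panel, ProteinPanel) else panel
    sd = npx.std(axis=0, ddof=1)
    bad = sd.index[(sd == 0) | ~np.isfinite(sd)]
    if len(bad):
        logger.warning("excluding %d zero-variance proteins: %s",
                       len(bad), list(bad[:5]))
        npx = npx.drop(columns=bad)
        sd = sd.drop(bad)
    return npx / sd


def fit_protein_associations(cohort: pd.DataFrame, std_npx: pd.DataFrame,
                             covariates=OBS_COVARIATES,
                             exclude_qc: pd.DataFrame | None = None,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Per-protein OLS slope of standardized protein on standardized BMI.

    Returns one row per protein: beta (SD protein per SD BMI), se, p
    (two-sided t), q_fdr (BH), bonf_sig and direction.  When ``exclude_qc``
    (a boolean subjects x proteins frame) is given, flagged cells are masked
    per protein — the sensitivity analysis that drops QC-warned samples.
    """
    if len(cohort) != len(std_npx):
        raise ValueError("cohort and protein matrix have different lengths")
    X, _ = design_matrix(cohort, covariates)
    zbmi = (cohort["bmi"] / cohort["bmi"].std(ddof=1)).to_numpy()
    Xf = np.column_stack([X, zbmi])
    Y = std_npx.to_numpy(float)

    if exclude_qc is None:
        beta, se, _, df = ols_multi(Xf, Y)
        b, s = beta[-1], se[-1]
        p = 2.0 * stats.t.sf(np.abs(b / s), df)
    else:
        mask = exclude_qc.reindex(columns=std_npx.columns,
                                  fill_value=False).to_numpy()
        b = np.empty(Y.shape[1])
        s = np.empty(Y.shape[1])
        p = np.empty(Y.shape[1])
        for j in range(Y.shape[1]):
            keep = ~mask[:, j]
            bj, sj, _, dfj = ols_multi(Xf[keep], Y[keep, j])
            b[j], s[j] = bj[-1, 0], sj[-1, 0]
            p[j] = 2.0 * stats.t.sf(abs(b[j] / s[j]), dfj)
    p = np.clip(p, 1e-320, 1.0)
    out = pd.DataFrame({
        "protein": std_npx.columns, "beta": b, "se": s, "p": p,
        "q_fdr": bh_qvalues(p),
        "bonf_sig": bonferroni_flags(p, alpha=alpha),
        "direction": np.where(b >= 0, "positive", "inverse"),
    })
    return out


@dataclass
class QuintileProfile:
    """Adjusted protein means by BMI quintile plus a between-quintile test."""

    table: pd.DataFrame      # quintile, n, bmi_mean, adj_mean, se
    f_stat: float
    f_p: float


def _quantile_strata(values: np.ndarray, k: int) -> np.ndarray:
    """Near-equal quantile strata; ties broken toward the lower stratum by a
    stable sort on (value, index). Sizes differ by at most one."""
    order = np.lexsort((np.arange(len(values)), values))
    strata = np.empty(len(values), dtype=int)
    for s, chunk in enumerate(np.array_split(order, k)):
        strata[chunk] = s
    return strata


def quintile_profile(cohort: pd.DataFrame, std_protein: pd.Series | np.ndarray,
                     covariates=None, k: int = 5) -> QuintileProfile:
    """Covariate-adjusted protein means within BMI quintiles.

    The protein is regressed on quintile indicators (no global intercept)
    plus mean-centered covariates; each indicator coefficient is then the
    adjusted least-squares mean at average covariate values.  Returns the
    mean BMI per quintile alongside, for plotting adjusted mean against
    mean BMI — the observational shape analysis.
    """
    bmi = cohort["bmi"].to_numpy(float)
    if len(np.unique(bmi)) < k:
        raise ValueError(f"need at least {k} distinct BMI values")
    y = np.asarray(std_protein, float)
    strata = _quantile_strata(bmi, k)
    counts = np.bincount(strata, minlength=k)
    if counts.min() < 10:
        logger.warning("a BMI quintile holds fewer than 10 subjects")

    D = np.zeros((len(bmi), k))
    D[np.arange(len(bmi)), strata] = 1.0
    if covariates:
        X, _ = design_matrix(cohort, covariates)
        C = X[:, 1:]                      # drop intercept, center the rest
        C = C - C.mean(axis=0)
        full = np.column_stack([D, C])
    else:
        full = D
    beta, se, resid, df = ols_multi(full, y)
    adj_mean, adj_se = beta[:k, 0], se[:k, 0]

    # between-quintile F-test: equality of the k adjusted means
    base = np.column_stack([np.ones(len(bmi))] + (
        [full[:, k:]] if full.shape[1] > k else []))
    _, _, r0, _ = ols_multi(base, y)
    rss1, rss0 = float(np.sum(resid ** 2)), float(np.sum(r0 ** 2))
    f = ((rss0 - rss1) / (k - 1)) / (rss1 / df)
    f_p = float(stats.f.sf(f, k - 1, df))

    table = pd.DataFrame({
        "quintile": np.arange(1, k + 1), "n": counts,
        "bmi_mean": [bmi[strata == s].mean() for s in range(k)],
        "adj_mean": adj_mean, "se": adj_se,
    })
    return QuintileProfile(table=table, f_stat=float(f), f_p=f_p)
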