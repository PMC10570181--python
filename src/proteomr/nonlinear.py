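"""Stratified non-linear MR: GS-free BMI strata, per-stratum ratio (LACE)
estimates, piecewise-linear causal curves, bootstrap bands and
trend/quadratic tests.

The residual-stratification method: GS-free BMI is the residual of BMI on
the genetic score, centered at the population mean, so stratification does
not condition on the instrument.  Within each quantile stratum the
localized average causal effect (LACE) is the stratum-specific
score-protein association divided by the full-sample score-BMI
association.  Stratum slopes are assembled into a continuous
piecewise-linear curve anchored at the population mean BMI, with
percentile bootstrap bands and inverse-variance-weighted meta-regression
tests for linear trend and curvature across strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from proteomr.observational import _quantile_strata
from proteomr.regression import STAGE1_COVARIATES, design_matrix, ols_multi

logger = logging.getLogger("proteomr")

__all__ = ["gs_free_residuals", "lace_estimates", "build_piecewise",
           "bootstrap_bands", "trend_quad_tests", "PiecewiseCurve"]


def gs_free_residuals(cohort: pd.DataFrame, score) -> pd.Series:
    """Residual of BMI on the genetic score, centered at the cohort mean BMI.

    The output has exactly the cohort's mean BMI and is orthogonal to the
    score — the stratification variable of the residual method.
    """
    g = np.asarray(score, float)
    y = cohort["bmi"].to_numpy(float)
    X = np.column_stack([np.ones(len(y)), g])
    beta, _, resid, _ = ols_multi(X, y)
    return pd.Series(resid[:, 0] + y.mean(), index=cohort.index,
                     name="gsfree_bmi")


def _stratum_numerators(cohort, g, y, strata, K, covariates):
    """Score-protein slope and SE within each stratum."""
    num = np.empty(K)
    num_se = np.empty(K)
    for s in range(K):
        idx = np.nonzero(strata == s)[0]
        sub = cohort.iloc[idx]
        if covariates:
            X, _ = design_matrix(sub, covariates)
        else:
            X = np.ones((len(idx), 1))
        Xf = np.column_stack([X, g[idx]])
        beta, se, _, _ = ols_multi(Xf, y[idx])
        num[s], num_se[s] = beta[-1, 0], se[-1, 0]
    return num, num_se


def lace_estimates(cohort: pd.DataFrame, score, std_protein, gsfree,
                   K: int = 5, covariates=STAGE1_COVARIATES,
                   second_order: bool = False) -> pd.DataFrame:
    """Per-stratum localized average causal effects.

    Strata are near-equal quantile bins of GS-free BMI (ties to the lower
    stratum).  The numerator is the within-stratum covariate-adjusted
    score-protein association; the denominator is the full-sample score-BMI
    association, shared across strata.  ``se_lace`` is first-order delta
    method (numerator SE / |denominator|) by default; ``second_order=True``
    adds the denominator-variance term.
    """
    if K < 2:
        raise ValueError("need at least 2 strata")
    g = np.asarray(score, float)
    y = np.asarray(std_protein, float)
    x = np.asarray(gsfree, float)
    bmi = cohort["bmi"].to_numpy(float)
    strata = _quantile_strata(x, K)
    if np.bincount(strata, minlength=K).min() == 0:
        raise ValueError("empty stratum")

    if covariates:
        Xall, _ = design_matrix(cohort, covariates)
    else:
        Xall = np.ones((len(g), 1))
    beta_d, se_d, _, _ = ols_multi(np.column_stack([Xall, g]), bmi)
    den, den_se = float(beta_d[-1, 0]), float(se_d[-1, 0])
    if abs(den) / den_se < 2.0:
        logger.warning("unstable ratio: |denominator|/SE = %.2f < 2",
                       abs(den) / den_se)

    num, num_se = _stratum_numerators(cohort, g, y, strata, K, covariates)
    lace = num / den
    se_lace = num_se / abs(den)
    if second_order:
        se_lace = np.sqrt(se_lace ** 2 + (num ** 2) * den_se ** 2 / den ** 4)

    lo = np.array([x[strata == s].min() for s in range(K)])
    hi = np.array([x[strata == s].max() for s in range(K)])
    return pd.DataFrame({
        "stratum": np.arange(1, K + 1),
        "low": lo, "high": hi,
        "x_mean": [x[strata == s].mean() for s in range(K)],
        "n": np.bincount(strata, minlength=K),
        "beta_num": num, "se_num": num_se,
        "beta_den": den, "se_den": den_se,
        "lace": lace, "se_lace": se_lace,
    })


@dataclass
class PiecewiseCurve:
    """Continuous piecewise-linear causal curve over GS-free BMI strata."""

    breakpoints: np.ndarray          # K+1 BMI values
    slopes: np.ndarray               # K LACE values
    anchor: float                    # BMI at which the curve equals 0
    values: np.ndarray               # curve at the breakpoints
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    x2_trend: float | None = None
    p_trend: float | None = None
    x2_quad: float | None = None
    p_quad: float | None = None
    B: int | None = None
    seed: int | None = None
    stratum_se: np.ndarray | None = field(default=None)

    def __call__(self, bmi):
        return _polyline(self.breakpoints, self.values,
                         np.asarray(bmi, float))


def _polyline(bp, vals, x):
    return np.interp(x, bp, vals)


def _assemble(bp: np.ndarray, slopes: np.ndarray, anchor: float) -> np.ndarray:
    """Accumulate segment rises, then translate so the curve is 0 at the
    anchor; each segment begins exactly where the previous one ends."""
    vals = np.concatenate([[0.0], np.cumsum(slopes * np.diff(bp))])
    shift = _polyline(bp, vals, np.array([anchor]))[0]
    return vals - shift


def build_piecewise(estimates: pd.DataFrame, anchor_bmi: float) -> PiecewiseCurve:
    """Assemble stratum LACE slopes into a continuous anchored curve.

    Breakpoints span the stratum ranges; segment k carries slope lace_k.
    The curve is translated so its value at ``anchor_bmi`` (the population
    mean BMI) is zero.
    """
    est = estimates.sort_values("stratum").reset_index(drop=True)
    lo, hi = est["low"].to_numpy(), est["high"].to_numpy()
    if np.any(lo[1:] < hi[:-1] - 1e-9):
        raise ValueError("stratum ranges overlap; strata must be contiguous")
    bp = np.concatenate([[lo[0]], 0.5 * (hi[:-1] + lo[1:]), [hi[-1]]])
    slopes = est["lace"].to_numpy()
    vals = _assemble(bp, slopes, anchor_bmi)
    return PiecewiseCurve(breakpoints=bp, slopes=slopes,
                          anchor=float(anchor_bmi), values=vals)


def bootstrap_bands(cohort: pd.DataFrame, score, std_protein, gsfree,
                    K: int = 5, B: int = 1000, seed: int = 0,
                    covariates=STAGE1_COVARIATES, anchor_bmi=None,
                    refit_denominator: bool = False) -> PiecewiseCurve:
    """Percentile bootstrap bands for the piecewise causal curve.

    Subjects are resampled with replacement within each GS-free BMI
    stratum; the stratum numerators are re-estimated (the full-sample
    denominator is held fixed by default) and the curve reassembled on the
    original breakpoints.  Bands are the 2.5/97.5 percentiles at each
    breakpoint, widened if necessary to contain the point curve.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    est = lace_estimates(cohort, score, std_protein, gsfree, K=K,
                         covariates=covariates)
    if anchor_bmi is None:
        anchor_bmi = float(cohort["bmi"].mean())
    curve = build_piecewise(est, anchor_bmi)

    g = np.asarray(score, float)
    y = np.asarray(std_protein, float)
    x = np.asarray(gsfree, float)
    bmi = cohort["bmi"].to_numpy(float)
    strata = _quantile_strata(x, K)
    counts = np.bincount(strata, minlength=K)
    if counts.min() < 30:
        logger.warning("a stratum holds fewer than 30 subjects")
    rng = np.random.default_rng(seed)
    den = est["beta_den"].iloc[0]

    boot_vals = np.empty((B, K + 1))
    boot_slopes = np.empty((B, K))
    members = [np.nonzero(strata == s)[0] for s in range(K)]
    for b in range(B):
        idx = np.concatenate([rng.choice(mem, size=len(mem), replace=True)
                              for mem in members])
        sub_strata = np.concatenate([np.full(len(mem), s)
                                     for s, mem in enumerate(members)])
        sub = cohort.iloc[idx]
        num, _ = _stratum_numerators(sub, g[idx], y[idx], sub_strata, K,
                                     covariates)
        if refit_denominator:
            if covariates:
                Xb, _ = design_matrix(sub, covariates)
            else:
                Xb = np.ones((len(idx), 1))
            bd, _, _, _ = ols_multi(np.column_stack([Xb, g[idx]]), bmi[idx])
            den_b = float(bd[-1, 0])
        else:
            den_b = den
        slopes = num / den_b
        boot_slopes[b] = slopes
        boot_vals[b] = _assemble(curve.breakpoints, slopes, anchor_bmi)

    lo = np.percentile(boot_vals, 2.5, axis=0)
    hi = np.percentile(boot_vals, 97.5, axis=0)
    curve.ci_lower = np.minimum(lo, curve.values)
    curve.ci_upper = np.maximum(hi, curve.values)
    curve.stratum_se = boot_slopes.std(axis=0, ddof=1)
    curve.B = B
    curve.seed = seed
    x2t, pt, x2q, pq = trend_quad_tests(est)
    curve.x2_trend, curve.p_trend = x2t, pt
    curve.x2_quad, curve.p_quad = x2q, pq
    return curve


def trend_quad_tests(estimates: pd.DataFrame):
    """Chi-square trend and quadratic tests across strata.

    Inverse-variance-weighted meta-regression of the LACE estimates on the
    stratum mean GS-free BMI: the trend statistic is the 1-df Wald
    chi-square for the linear term; the quadratic statistic is the 1-df
    Wald chi-square for the squared term in a quadratic meta-regression
    (omitted with fewer than 3 strata).
    """
    est = estimates.sort_values("stratum")
    lace = est["lace"].to_numpy(float)
    se = est["se_lace"].to_numpy(float)
    x = est["x_mean"].to_numpy(float)
    if len(lace) < 2:
        raise ValueError("need at least 2 strata for the trend test")
    w = 1.0 / se ** 2
    xc = x - np.average(x, weights=w)

    def wald_last(X):
        # fixed-effect meta-regression: variances are known, so the Wald
        # statistic uses scale 1, not an estimated residual scale (which
        # is 0 for a saturated fit)
        fit = sm.WLS(lace, X, weights=w).fit()
        cov_fixed = np.linalg.inv(X.T @ (w[:, None] * X))
        return float(fit.params[-1] ** 2 / cov_fixed[-1, -1])

    x2_trend = wald_last(sm.add_constant(xc))
    p_trend = float(stats.chi2.sf(x2_trend, 1))
    if len(lace) < 3:
        return x2_trend, p_trend, None, None
    x2_quad = wald_last(np.column_stack([np.ones_like(xc), xc, xc ** 2]))
    p_quad = float(stats.chi2.sf(x2_quad, 1))
    return x2_trend, p_trend, x2_quad, p_quad
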