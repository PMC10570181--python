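"""Genetic-score construction, instrument diagnostics and one-sample
two-stage least squares MR.

The instrument is a single weighted allele score: dosages of BMI-associated
variants (MAF >= 0.01) weighted by their external-study effect sizes.
Stage 1 regresses BMI on the score with the stage-1 covariate set (which
includes 12 ancestry principal components); stage 2 regresses each
standardized protein on the predicted BMI with the stage-2 set (plate in,
principal components out).  Standard errors use the standard 2SLS
correction: stage-2 residuals are computed at the observed, not predicted,
exposure.  Estimates are reported per a configurable BMI increment
(default 3.6 kg/m^2, the increment used for comparability with the
per-SD observational estimates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from proteomr.regression import (STAGE1_COVARIATES, STAGE2_COVARIATES,
                                 design_matrix, ols_multi)
from proteomr.synthdata import GenotypeDosages

logger = logging.getLogger("proteomr")

__all__ = ["build_score", "stage1_fit", "tsls_protein",
           "InstrumentDiagnostics", "WEAK_INSTRUMENT_F"]

WEAK_INSTRUMENT_F = 10.0
DEFAULT_BMI_INCREMENT = 3.6   # kg/m^2, ~1 SD in the observational analyses


@dataclass
class InstrumentDiagnostics:
    """First-stage summary for the weighted genetic score."""

    beta_gs: float        # BMI (kg/m^2) per score unit
    se: float
    F: float              # (beta_gs / se)^2
    r2: float             # incremental BMI variance explained by the score
    n: int
    p: float
    predicted_bmi: np.ndarray


def build_score(dosages: GenotypeDosages, weights: pd.DataFrame,
                maf_min: float = 0.01) -> pd.Series:
    """Weighted allele score: sum of weight x effect-allele dosage.

    ``weights`` columns: variant_id, effect_allele, weight.  When the
    weight's effect allele is the variant's other allele the dosage is
    flipped to 2 - d; variants matching neither allele, absent from the
    dosage matrix, or below the MAF threshold are dropped with a count
    logged.
    """
    meta = dosages.variants.set_index("variant_id")
    score = np.zeros(len(dosages.dosages))
    n_used = n_dropped = n_rare = 0
    for row in weights.itertuples(index=False):
        vid = row.variant_id
        if vid not in meta.index or vid not in dosages.dosages.columns:
            n_dropped += 1
            continue
        v = meta.loc[vid]
        if v["maf"] < maf_min:
            n_rare += 1
            continue
        d = dosages.dosages[vid].to_numpy(float)
        if row.effect_allele == v["effect_allele"]:
            pass
        elif row.effect_allele == v["other_allele"]:
            d = 2.0 - d
        else:
            n_dropped += 1
            logger.warning("variant %s: weight allele %s matches neither "
                           "assay allele; dropped", vid, row.effect_allele)
            continue
        score += row.weight * d
        n_used += 1
    if n_rare:
        logger.info("excluded %d variants with MAF < %g", n_rare, maf_min)
    if n_dropped:
        logger.info("dropped %d unresolvable weight rows", n_dropped)
    if n_used == 0:
        raise ValueError("no usable variants in the weight file")
    return pd.Series(score, index=dosages.dosages.index, name="gs")


def stage1_fit(cohort: pd.DataFrame, score,
               covariates=STAGE1_COVARIATES) -> InstrumentDiagnostics:
    """Regress BMI on the genetic score with the stage-1 adjustment set.

    Returns the score coefficient, its F statistic (squared t), the
    incremental R^2 of adding the score, and the fitted BMI values used as
    the stage-2 exposure.
    """
    g = np.asarray(score, float)
    if g.std() == 0:
        raise ValueError("genetic score has zero variance")
    y = cohort["bmi"].to_numpy(float)
    if covariates:
        X, _ = design_matrix(cohort, covariates)
    else:
        X = np.ones((len(y), 1))
    Xf = np.column_stack([X, g])
    beta, se, resid, df = ols_multi(Xf, y)
    b, s = float(beta[-1, 0]), float(se[-1, 0])
    F = (b / s) ** 2
    p = 2.0 * stats.t.sf(abs(b / s), df)
    sst = float(np.sum((y - y.mean()) ** 2))
    _, _, r0, _ = ols_multi(X, y)
    r2 = float((np.sum(r0 ** 2) - np.sum(resid ** 2)) / sst)
    pred = (Xf @ beta)[:, 0]
    return InstrumentDiagnostics(beta_gs=b, se=s, F=float(F), r2=r2,
                                 n=len(y), p=float(p), predicted_bmi=pred)


def tsls_protein(cohort: pd.DataFrame, diagnostics: InstrumentDiagnostics,
                 std_npx: pd.DataFrame | pd.Series,
                 covariates=STAGE2_COVARIATES,
                 bmi_increment: float = DEFAULT_BMI_INCREMENT) -> pd.DataFrame:
    """Stage-2 regression of standardized proteins on predicted BMI.

    The coefficient on predicted BMI is the causal effect per kg/m^2;
    reported effects are rescaled to ``bmi_increment`` kg/m^2.  The IV
    standard error replaces the naive stage-2 residuals with residuals
    computed at the observed BMI.  Weak instruments (F < 10) flag every
    emitted row rather than aborting.
    """
    Y = std_npx.to_frame() if isinstance(std_npx, pd.Series) else std_npx
    names = list(Y.columns)
    Ymat = Y.to_numpy(float)
    if covariates:
        X, _ = design_matrix(cohort, covariates)
    else:
        X = np.ones((len(cohort), 1))
    pred = diagnostics.predicted_bmi
    Xf = np.column_stack([X, pred])
    beta, _, _, _ = ols_multi(Xf, Ymat)
    b = beta[-1]

    # IV correction: residuals at observed BMI, same coefficient vector
    Xobs = np.column_stack([X, cohort["bmi"].to_numpy(float)])
    resid_iv = Ymat - Xobs @ beta
    n, k = Xf.shape
    sigma2 = np.einsum("ij,ij->j", resid_iv, resid_iv) / (n - k)
    XtXi_last = np.linalg.inv(Xf.T @ Xf)[-1, -1]
    s = np.sqrt(XtXi_last * sigma2)
    z = b / s
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-320, 1.0)

    weak = diagnostics.F < WEAK_INSTRUMENT_F
    if weak:
        logger.warning("weak instrument: first-stage F=%.2f < %g",
                       diagnostics.F, WEAK_INSTRUMENT_F)
    return pd.DataFrame({
        "protein": names,
        "beta": b * bmi_increment, "se": s * bmi_increment,
        "p": p, "method": "2SLS", "n": n,
        "weak_instrument": weak,
    })
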