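"""Two-sample bi-directional MR from GWAS summary statistics.

Covers allele harmonisation between exposure and outcome studies, the
single-instrument Wald ratio, Steiger filtering of causal direction, and
the bi-directional protein <-> BMI scan: each protein is instrumented by
its lead cis-pQTL (within +/-500 kb of the encoding gene) in the
protein-to-BMI direction, and by the genome-wide-significant BMI variants
(inverse-variance-weighted Wald ratios) in the BMI-to-protein direction,
with BH FDR within each direction and Steiger checks on the cis
instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from proteomr.multiplicity import bh_qvalues, bonferroni_flags

logger = logging.getLogger("proteomr")

__all__ = ["harmonize", "wald_ratio", "steiger_filter", "bidirectional_scan",
           "HarmonizedPair", "SteigerRecord"]

PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}
AMBIGUOUS_EAF = 0.42
GWS_P = 5e-8


@dataclass
class HarmonizedPair:
    """Allele-aligned exposure/outcome rows plus the dropped-SNP audit."""

    table: pd.DataFrame                    # one row per retained SNP
    dropped: list = field(default_factory=list)   # (snp_id, reason)


@dataclass
class SteigerRecord:
    snp: str
    r2_exposure: float
    r2_outcome: float
    z: float
    p: float
    direction_ok: bool


def _is_palindromic(ea: str, oa: str) -> bool:
    return frozenset((ea, oa)) in PALINDROMIC


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> HarmonizedPair:
    """Align outcome effect alleles to the exposure study.

    Swap-matched alleles flip the outcome beta and complement its EAF.
    Palindromic variants are dropped as ambiguous when min(EAF, 1-EAF)
    exceeds 0.42 in either study; unambiguous palindromic rows are aligned
    by allele and re-flipped if the allele frequencies disagree in side.
    Rows whose alleles match neither way are dropped with a reason.
    Harmonising an already-harmonised pair is a no-op.
    """
    merged = exposure.merge(outcome, on="snp_id",
                            suffixes=("_exp", "_out"), how="inner")
    if merged.empty:
        raise ValueError("no shared SNPs between exposure and outcome")
    rows, dropped = [], []
    for r in merged.itertuples(index=False):
        ea_e, oa_e = r.effect_allele_exp, r.other_allele_exp
        ea_o, oa_o = r.effect_allele_out, r.other_allele_out
        beta_o, eaf_o = r.beta_out, r.eaf_out
        flipped = False
        if (ea_o, oa_o) == (ea_e, oa_e):
            pass
        elif (ea_o, oa_o) == (oa_e, ea_e):
            beta_o, eaf_o, flipped = -beta_o, 1.0 - eaf_o, True
        else:
            dropped.append((r.snp_id, "allele-mismatch"))
            continue
        if _is_palindromic(ea_e, oa_e):
            if (min(r.eaf_exp, 1 - r.eaf_exp) > AMBIGUOUS_EAF
                    or min(eaf_o, 1 - eaf_o) > AMBIGUOUS_EAF):
                dropped.append((r.snp_id, "palindromic-ambiguous"))
                continue
            if (r.eaf_exp < 0.5) != (eaf_o < 0.5):
                # frequencies disagree in side: strand flip assumed
                beta_o, eaf_o, flipped = -beta_o, 1.0 - eaf_o, not flipped
        rows.append({
            "snp_id": r.snp_id,
            "effect_allele": ea_e, "other_allele": oa_e,
            "eaf_exp": r.eaf_exp, "beta_exp": r.beta_exp,
            "se_exp": r.se_exp, "p_exp": r.p_exp,
            "n_exp": getattr(r, "n_exp", np.nan),
            "eaf_out": eaf_o, "beta_out": beta_o,
            "se_out": r.se_out, "p_out": r.p_out,
            "n_out": getattr(r, "n_out", np.nan),
            "flipped": flipped,
        })
    if dropped:
        logger.info("harmonisation dropped %d SNPs", len(dropped))
    return HarmonizedPair(table=pd.DataFrame(rows), dropped=dropped)


def wald_ratio(b_exp: float, se_exp: float, b_out: float, se_out: float,
               second_order: bool = False) -> dict:
    """Single-instrument causal estimate: outcome beta / exposure beta.

    First-order delta-method SE is se_out/|b_exp|; the second-order form
    adds the exposure-uncertainty term.  Two-sided normal p-value.
    """
    if b_exp == 0:
        raise ValueError("Wald ratio undefined: exposure beta is zero")
    beta = b_out / b_exp
    se = abs(se_out / b_exp)
    if second_order:
        se = np.sqrt(se_out ** 2 / b_exp ** 2
                     + b_out ** 2 * se_exp ** 2 / b_exp ** 4)
    z = beta / se
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), 1e-320, 1.0))
    return {"beta": float(beta), "se": float(se), "p": p,
            "method": "wald_ratio"}


def _r2_from_z(z: float, n: float) -> float:
    r2 = z * z / (z * z + n - 2.0)
    if not 0.0 <= r2 < 1.0:
        logger.warning("variance explained clipped into [0, 1)")
    return float(np.clip(r2, 0.0, 1.0 - 1e-12))


def steiger_filter(b_exp, se_exp, n_exp, b_out, se_out, n_out,
                   snp: str = "", alpha: float = 0.05) -> SteigerRecord:
    """Orient the causal direction of one variant.

    Per-trait variance explained is recovered from the association z
    statistic, r^2 = z^2/(z^2 + n - 2); the Steiger test compares the
    Fisher-transformed correlations scaled by their sampling variances.
    ``direction_ok`` means exposure -> outcome is supported: the variant
    explains significantly more variance in the exposure.
    """
    if n_exp <= 10 or n_out <= 10:
        raise ValueError("sample sizes must exceed 10")
    r2e = _r2_from_z(b_exp / se_exp, n_exp)
    r2o = _r2_from_z(b_out / se_out, n_out)
    z = ((np.arctanh(np.sqrt(r2e)) - np.arctanh(np.sqrt(r2o)))
         / np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3)))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerRecord(snp=snp, r2_exposure=r2e, r2_outcome=r2o,
                         z=float(z), p=p,
                         direction_ok=bool(r2e > r2o and p < alpha))


def _ivw(ratios: list[dict]) -> dict:
    """Inverse-variance-weighted mean of per-variant Wald ratios (the
    summary-statistic analogue of multi-instrument 2SLS)."""
    b = np.array([r["beta"] for r in ratios])
    w = np.array([1.0 / r["se"] ** 2 for r in ratios])
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(np.clip(2.0 * stats.norm.sf(abs(beta / se)), 1e-320, 1.0))
    return {"beta": beta, "se": se, "p": p,
            "method": "ivw" if len(ratios) > 1 else "wald_ratio"}


def bidirectional_scan(protein_sumstats: dict[str, pd.DataFrame],
                       bmi_sumstats: pd.DataFrame,
                       cis_windows: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Bi-directional protein <-> BMI MR scan with FDR control.

    ``cis_windows`` columns: protein, chrom, start, end (1-based closed
    intervals, typically gene +/- 500 kb).  For each protein the lead
    (smallest-p) cis variant instruments the protein-to-BMI direction; the
    genome-wide-significant BMI variants outside the cis window instrument
    the BMI-to-protein direction.  Returns one row per protein and
    direction with Wald/IVW estimates, Steiger fields (cis direction), BH
    q-values within direction, Bonferroni flags, and a ``bidirectional``
    flag for proteins significant both ways.
    """
    win = cis_windows.set_index("protein")
    records = []
    for prot, ptab in protein_sumstats.items():
        if prot not in win.index:
            logger.info("protein %s has no cis window; skipped", prot)
            continue
        w = win.loc[prot]
        in_cis = ptab[(ptab["chrom"].astype(str) == str(w["chrom"]))
                      & (ptab["pos"] >= w["start"])
                      & (ptab["pos"] <= w["end"])]
        if in_cis.empty:
            logger.info("no cis variant for %s; skipped", prot)
            continue
        lead = in_cis.loc[[in_cis["p"].idxmin()]]
        pair = harmonize(lead, bmi_sumstats)
        if not pair.table.empty:
            r = pair.table.iloc[0]
            wr = wald_ratio(r["beta_exp"], r["se_exp"],
                            r["beta_out"], r["se_out"])
            st = steiger_filter(r["beta_exp"], r["se_exp"], r["n_exp"],
                                r["beta_out"], r["se_out"], r["n_out"],
                                snp=r["snp_id"])
            records.append({
                "protein": prot, "direction": "protein_to_bmi",
                "snp": r["snp_id"], "effect_allele": r["effect_allele"],
                "eaf": r["eaf_exp"], "beta_exp": r["beta_exp"],
                "se_exp": r["se_exp"], "n_snps": 1, **wr,
                "steiger_r2_exp": st.r2_exposure,
                "steiger_r2_out": st.r2_outcome,
                "steiger_p": st.p, "steiger_ok": st.direction_ok,
            })
        # BMI -> protein: genome-wide significant BMI variants off-window
        inst = bmi_sumstats[bmi_sumstats["p"] < GWS_P]
        inst = inst[~((inst["chrom"].astype(str) == str(w["chrom"]))
                      & (inst["pos"] >= w["start"])
                      & (inst["pos"] <= w["end"]))]
        if inst.empty:
            continue
        pair = harmonize(inst, ptab)
        ratios = [wald_ratio(r.beta_exp, r.se_exp, r.beta_out, r.se_out)
                  for r in pair.table.itertuples(index=False)
                  if r.beta_exp != 0]
        if not ratios:
            continue
        est = _ivw(ratios)
        records.append({
            "protein": prot, "direction": "bmi_to_protein",
            "snp": ";".join(pair.table["snp_id"].head(3)) + (
                "..." if len(pair.table) > 3 else ""),
            "effect_allele": "", "eaf": np.nan, "beta_exp": np.nan,
            "se_exp": np.nan, "n_snps": len(ratios), **est,
            "steiger_r2_exp": np.nan, "steiger_r2_out": np.nan,
            "steiger_p": np.nan, "steiger_ok": True,
        })
    out = pd.DataFrame(records)
    if out.empty:
        return out
    out["q_fdr"] = np.nan
    out["bonf_sig"] = False
    for d in out["direction"].unique():
        m = out["direction"] == d
        out.loc[m, "q_fdr"] = bh_qvalues(out.loc[m, "p"])
        out.loc[m, "bonf_sig"] = bonferroni_flags(out.loc[m, "p"],
                                                  alpha=alpha)
    out["significant"] = out["q_fdr"] < alpha
    sig_by_dir = out[out["significant"]].groupby("protein")["direction"].nunique()
    bidir = set(sig_by_dir[sig_by_dir >= 2].index)
    out["bidirectional"] = out["protein"].isin(bidir)
    return out
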