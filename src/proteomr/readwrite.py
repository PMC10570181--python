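"""Readers and writers for the tabular formats the pipeline touches.

Summary-statistic TSVs (SNP, alleles, EAF, beta, SE, p, ...), GMT gene-set
collections, NPX matrices, cohort CSVs, dosage matrices, score-weight
files, ground-truth JSON, and the deterministic results writers.  All
readers validate row invariants and drop offending rows with a logged
count and reason; all numeric output is formatted to 6 significant digits
so identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from proteomr.synthdata import GenotypeDosages, ProteinPanel, SimulationTruth

logger = logging.getLogger("proteomr")

__all__ = ["read_sumstats", "read_gmt", "write_results", "read_results",
           "write_sumstats", "write_cohort", "read_cohort", "write_npx",
           "read_npx", "write_dosages", "read_dosages", "write_weights",
           "read_weights", "write_truth_json"]

SUMSTAT_REQUIRED = ("snp_id", "effect_allele", "other_allele",
                    "eaf", "beta", "se", "p")
SUMSTAT_NUMERIC = ("eaf", "beta", "se", "p")
FLOAT_FMT = "%.6g"

RESULT_COLUMNS = {
    "association": ["protein", "beta", "se", "p", "q_fdr", "bonf_sig",
                    "direction"],
    "mr": ["protein", "beta", "se", "p", "method", "n", "weak_instrument"],
    "stratum": ["stratum", "low", "high", "x_mean", "n", "beta_num",
                "se_num", "beta_den", "se_den", "lace", "se_lace"],
    "scan": ["protein", "direction", "snp", "effect_allele", "eaf",
             "beta_exp", "se_exp", "n_snps", "beta", "se", "p", "method",
             "steiger_r2_exp", "steiger_r2_out", "steiger_p", "steiger_ok",
             "q_fdr", "bonf_sig", "significant", "bidirectional"],
    "coloc": ["snp_id", "h4_weight"],
    "enrichment": ["term", "description", "k", "K", "n", "N", "p", "q",
                   "significant", "members_hit"],
}


def read_sumstats(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a GWAS summary-statistic TSV/CSV.

    ``dialect`` optionally maps canonical column names to the file's
    header names.  Rows violating invariants (non-positive SE, EAF outside
    (0,1), identical alleles, p outside (0,1], NaN numerics) are dropped
    with a logged count per reason; a missing required column is a hard
    error naming the column.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    for col in SUMSTAT_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"summary-stat file missing required column "
                             f"{col!r}")
    if df.empty:
        logger.warning("summary-stat file %s holds no data rows", path)
        return df
    for col in SUMSTAT_NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    reasons = {
        "NaN numeric field": df[list(SUMSTAT_NUMERIC)].isna().any(axis=1),
        "nonpositive SE": df["se"] <= 0,
        "EAF outside (0,1)": (df["eaf"] <= 0) | (df["eaf"] >= 1),
        "identical alleles": df["effect_allele"] == df["other_allele"],
        "p outside (0,1]": (df["p"] <= 0) | (df["p"] > 1),
    }
    bad = pd.Series(False, index=df.index)
    for reason, mask in reasons.items():
        mask = mask.fillna(True) & ~bad
        if mask.any():
            logger.warning("dropped %d rows: %s", int(mask.sum()), reason)
        bad |= mask
    return df[~bad].reset_index(drop=True)


def write_sumstats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_gmt(path) -> dict:
    """Read a GMT gene-set file: term, description, members (tab-separated).

    Returns term id -> (description, member list).  Duplicate members
    within a term are deduplicated with a warning; a line with fewer than
    three fields is an error carrying the line number.
    """
    collection = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {i}: fewer than 3 fields")
            term, desc, members = fields[0], fields[1], fields[2:]
            seen, uniq = set(), []
            for m in members:
                if m in seen:
                    logger.warning("GMT term %s: duplicate member %s",
                                   term, m)
                    continue
                seen.add(m)
                uniq.append(m)
            collection[term] = (desc, uniq)
    return collection


def write_results(records: pd.DataFrame, path, kind: str) -> None:
    """Deterministic results writer.

    Fixed column order per result kind, floats at 6 significant digits,
    rows sorted by (p, id) when a p column exists; identical inputs give
    byte-identical files and a write-then-read round-trips at that
    precision.
    """
    if kind not in RESULT_COLUMNS:
        raise ValueError(f"unknown result kind {kind!r}; one of "
                         f"{sorted(RESULT_COLUMNS)}")
    cols = RESULT_COLUMNS[kind]
    df = pd.DataFrame(records).reindex(columns=cols)
    sort_cols = [c for c in ("p", cols[0]) if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- simulated-artifact round trips ----------------------------------------

def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, float_format="%.10g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df["bmi"].isna().any() or (df["bmi"] <= 0).any():
        raise ValueError("cohort BMI must be present and positive")
    return df


def write_npx(panel: ProteinPanel, prefix) -> None:
    """NPX matrix TSV (first column subject id) plus flag matrices."""
    prefix = Path(prefix)
    panel.npx.rename_axis("subject_id").to_csv(
        f"{prefix}_npx.tsv", sep="\t", float_format="%.10g")
    panel.lod_flag.rename_axis("subject_id").astype(int).to_csv(
        f"{prefix}_lod.tsv", sep="\t")
    panel.qc_warning.rename_axis("subject_id").astype(int).to_csv(
        f"{prefix}_qc.tsv", sep="\t")
    panel.panel.rename_axis("protein").to_csv(f"{prefix}_panels.tsv",
                                              sep="\t")


def read_npx(prefix) -> ProteinPanel:
    prefix = Path(prefix)
    npx = pd.read_csv(f"{prefix}_npx.tsv", sep="\t", index_col=0)
    lod = pd.read_csv(f"{prefix}_lod.tsv", sep="\t", index_col=0).astype(bool)
    qc = pd.read_csv(f"{prefix}_qc.tsv", sep="\t", index_col=0).astype(bool)
    panels = pd.read_csv(f"{prefix}_panels.tsv", sep="\t", index_col=0)
    return ProteinPanel(npx=npx, lod_flag=lod, qc_warning=qc,
                        panel=panels.iloc[:, 0])


def write_dosages(dosages: GenotypeDosages, prefix) -> None:
    prefix = Path(prefix)
    dosages.dosages.rename_axis("subject_id").to_csv(
        f"{prefix}_dosages.tsv", sep="\t", float_format="%.6g")
    dosages.variants.to_csv(f"{prefix}_variants.tsv", sep="\t", index=False,
                            float_format="%.10g")


def read_dosages(prefix) -> GenotypeDosages:
    prefix = Path(prefix)
    dos = pd.read_csv(f"{prefix}_dosages.tsv", sep="\t", index_col=0)
    var = pd.read_csv(f"{prefix}_variants.tsv", sep="\t",
                      dtype={"chrom": str})
    return GenotypeDosages(dosages=dos, variants=var)


def write_weights(weights: pd.Series, variants: pd.DataFrame, path) -> None:
    """Score-weight TSV: variant, effect allele, weight."""
    meta = variants.set_index("variant_id")
    df = pd.DataFrame({
        "variant_id": weights.index,
        "effect_allele": meta.loc[weights.index, "effect_allele"].to_numpy(),
        "weight": weights.to_numpy(),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("variant_id", "effect_allele", "weight"):
        if col not in df.columns:
            raise ValueError(f"weight file missing column {col!r}")
    if df["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids in weight file")
    df["weight"] = pd.to_numeric(df["weight"], errors="coerce")
    bad = ~np.isfinite(df["weight"])
    if bad.any():
        logger.warning("dropped %d weight rows with non-finite weight",
                       int(bad.sum()))
    return df[~bad].reset_index(drop=True)


def write_truth_json(truth: SimulationTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, default=str)
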