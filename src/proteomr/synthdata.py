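"""Synthetic cohort, genotype, proteome and GWAS summary-statistic generator.

Emulates the statistical structure of a proteome-wide adiposity study in a
relatively lean East-Asian cohort: BMI with mean 23.9 kg/m^2, SD 3.3 and
~6% obesity prevalence (a right tail heavier than normal, modelled as a
calibrated two-component normal mixture); a genetic score built from 816
independent variants explaining 3.7% of BMI variance; a protein panel in
log2 NPX units linearly affected by BMI with per-SD effects spanning
-0.45..+0.55; a minority of "reverse-causal" proteins that themselves
affect BMI and are instrumented by strong cis-pQTLs; below-LOD censoring
flags and sporadic QC warnings.

Ground truth (per-protein causal effects, score weights, cis assignments)
is recorded so recovery tests can compare estimates with the generating
parameters.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("proteomr")

__all__ = [
    "SimParams",
    "SimulationTruth",
    "GenotypeDosages",
    "ProteinPanel",
    "CalibrationError",
    "simulate_cohort",
    "simulate_proteins",
    "simulate_sumstats",
]

PANELS = ("Cardiometabolic", "Inflammation", "Neurology", "Oncology")
_BASES = np.array(list("ACGT"))
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPAL_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT"
                 if a != b and (a, b) not in _PALINDROMIC_PAIRS]


class CalibrationError(RuntimeError):
    """Raised when the (mean, SD, obese fraction) triple cannot be matched."""


@dataclass
class SimParams:
    """Generator parameters; defaults reproduce the study conditions."""

    n_subjects: int = 3977
    n_variants: int = 816
    maf_range: tuple = (0.01, 0.5)
    target_gs_r2: float = 0.037
    bmi_mean: float = 23.9          # kg/m^2
    bmi_sd: float = 3.3             # kg/m^2
    obese_frac: float = 0.06        # Pr(BMI >= 30)
    n_proteins: int = 100
    effect_range: tuple = (-0.45, 0.55)  # SD protein per SD BMI
    frac_null: float = 0.30
    n_reverse: int = 8
    cis_r2: float = 0.10            # protein variance from its cis-pQTL
    qc_warn_frac: float = 0.04      # flagged samples on the affected subset
    qc_protein_frac: float = 0.07   # fraction of proteins carrying warnings
    lod_quantile: float = 0.02
    palindromic_frac: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        fr = {"target_gs_r2": self.target_gs_r2, "obese_frac": self.obese_frac,
              "frac_null": self.frac_null, "cis_r2": self.cis_r2,
              "qc_warn_frac": self.qc_warn_frac,
              "qc_protein_frac": self.qc_protein_frac,
              "lod_quantile": self.lod_quantile,
              "palindromic_frac": self.palindromic_frac}
        for name, v in fr.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} outside [0.01, 0.5]")
        if self.n_reverse > self.n_proteins:
            raise ValueError("n_reverse exceeds n_proteins")
        if self.bmi_sd <= 0:
            raise ValueError("bmi_sd must be positive")
        if self.n_subjects < 2 or self.n_variants < 1 or self.n_proteins < 1:
            raise ValueError("n_subjects, n_variants, n_proteins too small")


@dataclass
class GenotypeDosages:
    """Dosage matrix (subjects x variants) plus per-variant metadata."""

    dosages: pd.DataFrame           # index subject_id, columns variant_id
    variants: pd.DataFrame          # variant_id, chrom, pos, EA, OA, maf


@dataclass
class ProteinPanel:
    """NPX matrix (log2 scale) with below-LOD and QC-warning flags."""

    npx: pd.DataFrame
    lod_flag: pd.DataFrame
    qc_warning: pd.DataFrame
    panel: pd.Series                # per-protein panel label


@dataclass
class SimulationTruth:
    """Ground-truth generating parameters, for recovery tests."""

    seed: int
    beta_bmi_to_protein: pd.Series  # SD protein per SD BMI; 0 for reverse set
    reverse_set: dict               # protein -> kg/m^2 BMI per SD protein
    gs_weights_true: pd.Series      # kg/m^2 per effect allele (score variants)
    cis_assignments: pd.DataFrame   # protein, variant_id, cis_r2, gene pos
    realized_gs_r2: float
    variants: pd.DataFrame
    params: SimParams
    covariate_effects: dict = field(default_factory=dict)
    mixture: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "beta_bmi_to_protein": self.beta_bmi_to_protein.to_dict(),
            "reverse_set": dict(self.reverse_set),
            "gs_weights_true": self.gs_weights_true.to_dict(),
            "cis_assignments": self.cis_assignments.to_dict(orient="records"),
            "realized_gs_r2": self.realized_gs_r2,
            "variants": self.variants.to_dict(orient="records"),
            "params": asdict(self.params),
            "covariate_effects": self.covariate_effects,
            "mixture": self.mixture,
        }


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG stream: adding a stage never perturbs earlier draws."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(zlib.crc32(name.encode()),)))


def _calibrate_mixture(mean: float, sd: float, obese_frac: float,
                       var_other: float, threshold: float = 30.0) -> dict:
    """Two-component normal mixture for the BMI residual.

    BMI = mean + (genetic + covariate + reverse-protein parts, jointly ~
    N(0, var_other)) + e, where e is a two-component mixture with shared
    component SD s, weights (1-w, w) and means (mu1, mu2) constrained to
    zero mean and the residual variance.  w and mu2 are solved numerically
    so that the marginal Pr(BMI >= threshold) matches ``obese_frac``.
    """
    var_e = sd ** 2 - var_other
    if var_e <= 0:
        raise CalibrationError(
            f"non-residual variance {var_other:.3f} exceeds total {sd**2:.3f}")
    d = threshold - mean

    def tail(w: float, mu2: float) -> float:
        mu1 = -w * mu2 / (1.0 - w)
        s2 = var_e - (1.0 - w) * mu1 ** 2 - w * mu2 ** 2
        if s2 <= 0:
            return np.nan
        sv = np.sqrt(var_other + s2)
        return ((1.0 - w) * stats.norm.sf((d - mu1) / sv)
                + w * stats.norm.sf((d - mu2) / sv))

    for w in (0.10, 0.05, 0.15, 0.20, 0.30, 0.02):
        mu_max = 0.999 * np.sqrt(var_e * (1.0 - w) / w)
        grid = np.linspace(-mu_max, mu_max, 201)
        vals = np.array([tail(w, m) for m in grid]) - obese_frac
        ok = np.isfinite(vals)
        sign = np.sign(vals[ok])
        idx = np.nonzero(np.diff(sign) != 0)[0]
        if idx.size == 0:
            continue
        gi = np.nonzero(ok)[0]
        a, b = grid[gi[idx[0]]], grid[gi[idx[0] + 1]]
        mu2 = optimize.brentq(lambda m: tail(w, m) - obese_frac, a, b,
                              xtol=1e-10)
        mu1 = -w * mu2 / (1.0 - w)
        s2 = var_e - (1.0 - w) * mu1 ** 2 - w * mu2 ** 2
        return {"w": w, "mu1": float(mu1), "mu2": float(mu2),
                "s": float(np.sqrt(s2)), "var_other": float(var_other)}
    raise CalibrationError(
        f"cannot reach Pr(BMI>={threshold})={obese_frac} with mean={mean}, "
        f"sd={sd}, var_other={var_other:.3f}")


def _make_variants(params: SimParams, rng: np.random.Generator,
                   protein_ids: list[str]) -> pd.DataFrame:
    """Variant metadata: score variants on chrom 1, cis variants on chrom 2.

    Each protein's encoding gene sits at a distinct position on a synthetic
    chromosome and its cis-pQTL lies within the +/-500 kb window around it.
    """
    m = params.n_variants
    rows = []
    mafs = rng.uniform(*params.maf_range, size=m)
    pal = rng.random(m + len(protein_ids)) < params.palindromic_frac
    for v in range(m):
        ea, oa = _draw_alleles(rng, pal[v])
        rows.append((f"gs_{v + 1:04d}", "1", 1_000_000 + v * 50_000,
                     ea, oa, mafs[v], False, None))
    cis_mafs = rng.uniform(0.05, 0.5, size=len(protein_ids))
    for j, prot in enumerate(protein_ids):
        gene_pos = 1_000_000 + j * 2_000_000
        offset = int(rng.integers(-400_000, 400_001))
        ea, oa = _draw_alleles(rng, pal[m + j])
        rows.append((f"cis_{prot}", "2", gene_pos + offset,
                     ea, oa, cis_mafs[j], True, gene_pos))
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos",
                                       "effect_allele", "other_allele",
                                       "maf", "is_cis", "gene_pos"])


def _draw_alleles(rng: np.random.Generator, palindromic: bool):
    pairs = _PALINDROMIC_PAIRS if palindromic else _NONPAL_PAIRS
    return pairs[int(rng.integers(len(pairs)))]


def simulate_cohort(params: SimParams):
    """Generate (Cohort, GenotypeDosages, SimulationTruth).

    The cohort table carries BMI, age, sex, study area, fasting time,
    ambient temperature, case-subcohort ascertainment flag, plate and 12
    ancestry principal components. BMI is assembled from a genetic score
    component (variance share ``target_gs_r2``), covariate contributions,
    reverse-protein contributions, and a mixture residual calibrated so the
    marginal matches the target mean, SD and obese fraction simultaneously.
    """
    params.validate()
    n = params.n_subjects
    seed = params.seed

    protein_ids = [f"PROT{j + 1:04d}" for j in range(params.n_proteins)]
    rng_var = _stream(seed, "variants")
    variants = _make_variants(params, rng_var, protein_ids)

    rng_geno = _stream(seed, "genotypes")
    dos = rng_geno.binomial(2, variants["maf"].to_numpy(),
                            size=(n, len(variants))).astype(float)
    subject_ids = [f"S{i + 1:05d}" for i in range(n)]
    dosages = pd.DataFrame(dos, index=subject_ids,
                           columns=variants["variant_id"])

    # --- genetic score component -------------------------------------------
    m = params.n_variants
    rng_w = _stream(seed, "weights")
    w_raw = rng_w.normal(0.0, 1.0, size=m) * np.sqrt(
        rng_w.uniform(0.2, 1.0, size=m))
    gs_dos = dos[:, :m]
    g_raw = (gs_dos - gs_dos.mean(0)) @ w_raw
    sd_raw = g_raw.std()
    if params.target_gs_r2 > 0 and sd_raw > 0:
        c = np.sqrt(params.target_gs_r2) * params.bmi_sd / sd_raw
    else:
        c = 0.0
    gs_weights_true = pd.Series(c * w_raw,
                                index=variants["variant_id"][:m].to_numpy())
    g = c * g_raw

    # --- covariates ---------------------------------------------------------
    rng_cov = _stream(seed, "covariates")
    age = np.clip(rng_cov.normal(57.3, 11.6, n), 30, 79)
    sex = (rng_cov.random(n) < 0.55).astype(int)      # 1 = female
    area = rng_cov.integers(0, 10, n)
    fasting = np.clip(rng_cov.normal(10.0, 3.0, n), 0.5, 24.0)
    temp = np.clip(rng_cov.normal(15.0, 8.0, n), -15, 40)
    ascert = (rng_cov.random(n) < 0.49).astype(int)    # 1 = case
    plate = rng_cov.permutation(np.arange(n) % 44)
    pcs = rng_cov.normal(0.0, 1.0, size=(n, 12))

    cov_eff = {"age": -0.01, "sex": 0.30, "fasting_time": 0.0,
               "ambient_temp": 0.01, "ascertainment": 0.40}
    c_part = (cov_eff["age"] * (age - age.mean())
              + cov_eff["sex"] * (sex - sex.mean())
              + cov_eff["ambient_temp"] * (temp - temp.mean())
              + cov_eff["ascertainment"] * (ascert - ascert.mean()))

    # --- reverse-causal proteins (protein -> BMI) ---------------------------
    rng_rev = _stream(seed, "reverse")
    rev_ids = [str(p) for p in rng_rev.choice(
        protein_ids, size=params.n_reverse, replace=False)] \
        if params.n_reverse else []
    rev_ids = sorted(rev_ids)
    # effect on BMI in SD-BMI units per SD protein, sign random
    rev_mag = rng_rev.uniform(0.05, 0.15, size=len(rev_ids))
    rev_sign = np.where(rng_rev.random(len(rev_ids)) < 0.5, -1.0, 1.0)
    reverse_set = {p: float(mag * s * params.bmi_sd)
                   for p, mag, s in zip(rev_ids, rev_mag, rev_sign)}

    rng_lat = _stream(seed, "reverse-latents")
    rev_latent = {}
    r_part = np.zeros(n)
    for p in rev_ids:
        d = dosages[f"cis_{p}"].to_numpy()
        sd_d = d.std()
        z = (d - d.mean()) / sd_d if sd_d > 0 else np.zeros(n)
        lat = (np.sqrt(params.cis_r2) * z
               + np.sqrt(1.0 - params.cis_r2) * rng_lat.normal(0, 1, n))
        rev_latent[p] = lat
        r_part += reverse_set[p] * lat

    # --- BMI assembly with calibrated mixture residual ----------------------
    var_other = float(np.var(g) + np.var(c_part) + np.var(r_part))
    mix = _calibrate_mixture(params.bmi_mean, params.bmi_sd,
                             params.obese_frac, var_other)
    rng_res = _stream(seed, "bmi-residual")
    comp = rng_res.random(n) < mix["w"]
    e = np.where(comp, mix["mu2"], mix["mu1"]) + mix["s"] * rng_res.normal(0, 1, n)
    bmi = params.bmi_mean + g + c_part + r_part + e

    cohort = pd.DataFrame({
        "subject_id": subject_ids, "bmi": bmi, "age": age, "sex": sex,
        "area": [f"area{a:02d}" for a in area], "fasting_time": fasting,
        "ambient_temp": temp, "ascertainment": ascert,
        "plate": [f"plate{p:02d}" for p in plate],
        **{f"pc{i + 1}": pcs[:, i] for i in range(12)},
    })

    # --- per-protein forward effects (drawn here so truth is complete) ------
    rng_eff = _stream(seed, "protein-effects")
    beta = rng_eff.uniform(*params.effect_range, size=params.n_proteins)
    n_null = int(round(params.frac_null * params.n_proteins))
    null_idx = rng_eff.choice(params.n_proteins, size=n_null, replace=False)
    beta[null_idx] = 0.0
    beta = pd.Series(beta, index=protein_ids)
    beta[rev_ids] = 0.0   # reverse proteins are not downstream of BMI

    cis = variants[variants["is_cis"]].copy()
    cis["protein"] = [v[len("cis_"):] for v in cis["variant_id"]]
    cis_assign = cis[["protein", "variant_id", "chrom", "pos",
                      "gene_pos", "maf"]].reset_index(drop=True)
    cis_assign["cis_r2"] = params.cis_r2

    if params.target_gs_r2 > 0:
        realized = _realized_r2(bmi, g)
    else:
        realized = 0.0
    truth = SimulationTruth(
        seed=seed, beta_bmi_to_protein=beta, reverse_set=reverse_set,
        gs_weights_true=gs_weights_true, cis_assignments=cis_assign,
        realized_gs_r2=realized, variants=variants, params=params,
        covariate_effects=cov_eff, mixture=mix)
    truth._reverse_latents = rev_latent   # reused by simulate_proteins
    return cohort, GenotypeDosages(dosages=dosages, variants=variants), truth


def _realized_r2(y: np.ndarray, x: np.ndarray) -> float:
    r = np.corrcoef(y, x)[0, 1]
    return float(r * r)


def simulate_proteins(cohort: pd.DataFrame, truth: SimulationTruth,
                      params: SimParams,
                      dosages: GenotypeDosages | None = None) -> ProteinPanel:
    """Generate the NPX protein panel given a cohort and its ground truth.

    Forward proteins respond linearly to BMI (in SD units) with a cis-pQTL
    contribution and Gaussian noise scaled so the latent variance is 1; the
    standardized regression slope on BMI therefore recovers the generating
    effect directly.  Reverse-set proteins reuse the latent values that were
    fed into BMI during cohort assembly, preserving protein -> BMI causal
    order.  Below-LOD values are flagged but retained; a random subset of
    proteins carries QC warnings on ``qc_warn_frac`` of samples.
    """
    if truth.seed != params.seed:
        raise ValueError("cohort truth and params come from different seeds")
    n = len(cohort)
    protein_ids = list(truth.beta_bmi_to_protein.index)
    if dosages is not None and not dosages.dosages.index.equals(
            pd.Index(cohort["subject_id"])):
        raise ValueError("dosage subjects do not match cohort subjects")

    zbmi = (cohort["bmi"] - cohort["bmi"].mean()) / cohort["bmi"].std()
    zbmi = zbmi.to_numpy()
    rng = _stream(params.seed, "proteins")
    intercepts = rng.uniform(-1.0, 6.0, size=len(protein_ids))
    # small covariate leakage onto proteins (not calibrated to any cohort)
    age_eff = rng.normal(0.0, 0.002, size=len(protein_ids))
    sex_eff = rng.normal(0.0, 0.05, size=len(protein_ids))
    age_c = (cohort["age"] - cohort["age"].mean()).to_numpy()
    sex_c = (cohort["sex"] - cohort["sex"].mean()).to_numpy()

    rev_latent = getattr(truth, "_reverse_latents", {})
    cis_lookup = truth.cis_assignments.set_index("protein")["variant_id"]

    npx = np.empty((n, len(protein_ids)))
    for j, prot in enumerate(protein_ids):
        if prot in rev_latent:
            latent = rev_latent[prot]
        else:
            b = truth.beta_bmi_to_protein[prot]
            cis_part = np.zeros(n)
            cis_share = 0.0
            if dosages is not None and prot in cis_lookup.index:
                d = dosages.dosages[cis_lookup[prot]].to_numpy()
                sd_d = d.std()
                if sd_d > 0:
                    cis_part = (np.sqrt(params.cis_r2)
                                * (d - d.mean()) / sd_d)
                    cis_share = params.cis_r2
            noise_var = max(1.0 - b * b - cis_share, 0.05)
            latent = (b * zbmi + cis_part
                      + np.sqrt(noise_var) * rng.normal(0, 1, n))
        npx[:, j] = (intercepts[j] + latent
                     + age_eff[j] * age_c + sex_eff[j] * sex_c)

    npx_df = pd.DataFrame(npx, index=cohort["subject_id"].to_numpy(),
                          columns=protein_ids)
    # below-LOD flags: lowest lod_quantile of each protein's distribution
    if params.lod_quantile > 0:
        lod = npx_df.quantile(params.lod_quantile, axis=0)
        lod_flag = npx_df.lt(lod, axis=1)
    else:
        lod_flag = pd.DataFrame(False, index=npx_df.index,
                                columns=npx_df.columns)
    rng_qc = _stream(params.seed, "qc")
    qc = pd.DataFrame(False, index=npx_df.index, columns=npx_df.columns)
    n_qc_prot = int(round(params.qc_protein_frac * len(protein_ids)))
    if n_qc_prot > 0 and params.qc_warn_frac > 0:
        qc_prots = rng_qc.choice(protein_ids, size=n_qc_prot, replace=False)
        for prot in qc_prots:
            hit = rng_qc.random(n) < params.qc_warn_frac
            qc.loc[hit, prot] = True
    panel = pd.Series([PANELS[j % len(PANELS)] for j in range(len(protein_ids))],
                      index=protein_ids, name="panel")
    return ProteinPanel(npx=npx_df, lod_flag=lod_flag, qc_warning=qc,
                        panel=panel)


def _sumstat_rows(rng, variants: pd.DataFrame, true_beta: np.ndarray,
                  n_sample: int, trait: str, flip: np.ndarray) -> pd.DataFrame:
    """Marginal per-allele association rows on a standardized trait scale."""
    f = variants["maf"].to_numpy()
    het = 2.0 * f * (1.0 - f)
    se = 1.0 / np.sqrt(n_sample * het)
    beta_hat = true_beta + se * rng.normal(0, 1, len(f))
    eaf = np.clip(f + rng.normal(0, np.sqrt(f * (1 - f) / (2 * n_sample))),
                  1e-3, 1 - 1e-3)
    ea = variants["effect_allele"].to_numpy().copy()
    oa = variants["other_allele"].to_numpy().copy()
    b, q = beta_hat.copy(), eaf.copy()
    ea[flip], oa[flip] = oa[flip].copy(), ea[flip].copy()
    b[flip] = -b[flip]
    q[flip] = 1.0 - q[flip]
    p = 2.0 * stats.norm.sf(np.abs(b / se))
    return pd.DataFrame({
        "snp_id": variants["variant_id"].to_numpy(),
        "chrom": variants["chrom"].to_numpy(),
        "pos": variants["pos"].to_numpy(),
        "effect_allele": ea, "other_allele": oa, "eaf": q,
        "beta": b, "se": se, "p": np.clip(p, 1e-320, 1.0),
        "n": n_sample, "trait": trait,
    })


def simulate_sumstats(truth: SimulationTruth, n_exposure: int,
                      n_outcome: int, seed: int, flip_frac: float = 0.3,
                      n_null_neighbors: int = 0):
    """Two-sample GWAS summary statistics for proteins and BMI.

    Returns ``(exposure, outcome)``: the exposure table holds per-protein
    association rows (each protein at its cis-pQTL, at the BMI score
    variants, and optionally at null neighbour SNPs for colocalisation
    regions); the outcome table holds BMI association rows at the same
    variants.  Effect alleles are randomly swapped between the two tables
    (fraction ``flip_frac``) and a fraction of variants is palindromic, so
    downstream harmonisation is exercised.  Sampling noise matches the
    stated sample sizes; only lead cis-pQTLs are emitted (no LD structure).
    """
    if n_exposure <= 0 or n_outcome <= 0:
        raise ValueError("sample sizes must be positive")
    params = truth.params
    rng = _stream(seed, "sumstats")
    bmi_sd = params.bmi_sd

    gs_vars = truth.variants[~truth.variants["is_cis"]].reset_index(drop=True)
    # per-allele effect on standardized BMI
    w_sd = truth.gs_weights_true.to_numpy() / bmi_sd
    cis = truth.cis_assignments
    cis_vars = truth.variants.set_index("variant_id").loc[
        cis["variant_id"]].reset_index()

    # per-allele effect of each cis variant on its standardized protein
    het = 2.0 * cis["maf"].to_numpy() * (1.0 - cis["maf"].to_numpy())
    b_cis_prot = np.sqrt(params.cis_r2 / het)
    # effect of cis variant on standardized BMI: via protein for reverse set
    delta_sd = np.array([truth.reverse_set.get(p, 0.0) / bmi_sd
                         for p in cis["protein"]])
    b_cis_bmi = b_cis_prot * delta_sd

    exp_parts, out_parts = [], []
    # --- BMI rows -----------------------------------------------------------
    flip = rng.random(len(gs_vars)) < flip_frac
    out_parts.append(_sumstat_rows(rng, gs_vars, w_sd, n_outcome, "BMI", flip))
    flip = rng.random(len(cis_vars)) < flip_frac
    out_parts.append(_sumstat_rows(rng, cis_vars, b_cis_bmi, n_outcome,
                                   "BMI", flip))

    # --- protein rows -------------------------------------------------------
    for i, prot in enumerate(cis["protein"]):
        b_fwd = truth.beta_bmi_to_protein[prot]
        # protein association at BMI score variants: mediated through BMI
        tb = w_sd * b_fwd
        flip = rng.random(len(gs_vars)) < flip_frac
        exp_parts.append(_sumstat_rows(rng, gs_vars, tb, n_exposure,
                                       prot, flip))
        own = cis_vars.iloc[[i]]
        flip = rng.random(1) < flip_frac
        exp_parts.append(_sumstat_rows(rng, own, np.array([b_cis_prot[i]]),
                                       n_exposure, prot, flip))
        if n_null_neighbors > 0:
            nb = _null_neighbors(rng, own.iloc[0], n_null_neighbors)
            flip = rng.random(len(nb)) < flip_frac
            exp_parts.append(_sumstat_rows(rng, nb, np.zeros(len(nb)),
                                           n_exposure, prot, flip))
            flip = rng.random(len(nb)) < flip_frac
            out_parts.append(_sumstat_rows(rng, nb, np.zeros(len(nb)),
                                           n_outcome, "BMI", flip))
    exposure = pd.concat(exp_parts, ignore_index=True)
    outcome = pd.concat(out_parts, ignore_index=True)
    return exposure, outcome


def _null_neighbors(rng, cis_row: pd.Series, k: int) -> pd.DataFrame:
    """Null SNPs in the cis region around a lead variant."""
    rows = []
    for t in range(k):
        ea, oa = _draw_alleles(rng, False)
        rows.append((f"{cis_row['variant_id']}_nb{t + 1:02d}",
                     cis_row["chrom"],
                     int(cis_row["pos"]) + (t + 1) * 7_000 * (-1) ** t,
                     ea, oa, float(rng.uniform(0.05, 0.5)), True, None))
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos",
                                       "effect_allele", "other_allele",
                                       "maf", "is_cis", "gene_pos"])
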