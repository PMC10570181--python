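# Methods

This note documents the models, numerical choices and limitations behind
`proteomr`. Empirical statements here are limited to what the test suite
and `scripts/acceptance.py` themselves compute.

## Synthetic study design

The generator emulates a case-subcohort proteomics study in a relatively
lean adult population. Defaults (in `SimParams`) are the study
conditions, not free dials:

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 3977 | analysis sample |
| `n_variants` | 816 | score variants, MAF uniform on [0.01, 0.5] |
| `target_gs_r2` | 0.037 | BMI variance share of the genetic score |
| `bmi_mean`, `bmi_sd` | 23.9, 3.3 kg/m² | marginal BMI moments |
| `obese_frac` | 0.06 | Pr(BMI ≥ 30 kg/m²) |
| `effect_range` | [−0.45, 0.55] | protein effect per SD BMI |
| `frac_null` | 0.30 | proteins with no BMI effect |
| `n_reverse` | 8 | reverse-causal (protein→BMI) proteins |
| `cis_r2` | 0.10 | protein variance share of its cis-pQTL |
| `qc_warn_frac` | 0.04 | flagged samples on the warned protein subset |
| `lod_quantile` | 0.02 | below-LOD flagging quantile |

**BMI marginal.** A normal with mean 23.9 and SD 3.3 puts only ~3.2% of
mass above 30, so the residual is a two-component normal mixture with
shared component SD. Given the variance already committed to the genetic,
covariate and reverse-protein parts, the mixture weight and means are
solved numerically (grid + Brent root-finding on the exact tail
probability of the convolution) so that the marginal mean, SD and obese
fraction hold simultaneously. An infeasible triple raises
`CalibrationError` with the attempted parameters.

**Genetic score.** Dosages are independent binomial(2, MAF) draws (no LD
— a stated non-goal). Raw variant effects are scaled as a block so the
centered score's variance share of BMI equals `target_gs_r2`; the emitted
weight file carries these per-allele effects (kg/m² per effect allele),
emulating externally derived weights.

**Causal order.** Reverse-set proteins are drawn first as latent
variables (cis variant share `cis_r2`, unit variance), contribute their
effect to BMI (defaults: |effect| uniform on 0.05–0.15 SD BMI per SD
protein, the magnitude regime of printed cis-pQTL Wald ratios at
biobank-scale outcome samples), and are exposed unchanged as NPX values —
so protein→BMI is the generative direction. Forward proteins are drawn
after BMI with noise SD √(1 − β² − cis share), making the latent variance
1 so the standardized regression slope recovers β directly.

**Covariates** (age, sex, study area, fasting time, ambient temperature,
ascertainment flag, plate, 12 ancestry PCs) carry small fixed effects on
BMI and small random leakage onto proteins. These are plausible
placeholders, configurable, and not calibrated to any cohort — analyses
adjust for them, so their exact sizes do not drive any tested claim.

**Summary statistics** are emitted on the standardized-trait scale with
per-allele SE 1/√(n·2f(1−f)), noise matching the stated sample sizes, and
only lead cis-pQTLs (conditional pQTL discovery is out of scope). Effect
alleles are randomly swapped between the exposure and outcome tables and
~5% of variants are palindromic, so harmonisation is always exercised.
Reproducibility uses one master seed with named child streams
(CRC32-keyed `SeedSequence`), so adding a stage never perturbs earlier
draws.

## Estimators

**Observational scan.** Proteins are standardized by division by their
sample SD (means unshifted, per the source convention); BMI enters in SD
units. OLS is vectorised across proteins from one design factorisation.
Categorical covariates enter as first-reference dummy sets; age² is
computed on centered age (identical estimates, better conditioning);
collinear columns are dropped with a log message. Below-LOD values are
retained; QC-warned cells can be masked as a sensitivity flag (default
off, matching the main-analysis convention).

**Two-stage least squares.** Stage 1 includes the 12 PCs and excludes
plate; stage 2 includes plate and excludes PCs (the quoted adjustment
sets). The IV standard error uses stage-2 residuals computed at the
*observed* exposure — the standard 2SLS correction; the naive
predicted-residual SE is wrong and the discrepancy is asserted in tests.
Effects are rescaled to a configurable BMI increment, default 3.6 kg/m²
(kept as printed even though the cohort SD prints as 3.3; the constant is
a config value). First-stage F < 10 flags, rather than suppresses,
results.

**Non-linear MR.** Residual stratification (not doubly-ranked): GS-free
BMI is the residual of BMI on the score alone (no covariates — the
narrower reading of the source description), centered at the cohort mean.
Strata are near-equal quantile bins; ties break toward the lower stratum
via a stable sort on (value, index), so sizes differ by ≤1. Stratum
numerators adjust for the full stage-1 covariate set; the denominator is
the full-sample stage-1 coefficient, shared across strata. `se_lace` is
first-order delta method (numerator SE / |denominator|) by default — with
first-stage F ≈ 150 the denominator term is negligible; a second-order
option exists. The piecewise curve uses segment slopes LACE_k between the
stratum boundary midpoints, accumulated left to right (continuity is
algebraic) and translated so the curve is zero at the anchor (population
mean BMI). The bootstrap resamples subjects within stratum and
re-estimates numerators only, holding the denominator fixed (the
described scope); full re-estimation is behind a flag. Bands are
pointwise 2.5/97.5 percentiles at the breakpoints, widened if needed to
contain the point curve; they are *not* simultaneous bands, and the test
suite checks pointwise coverage. Trend and quadratic tests are 1-df Wald
χ² from fixed-effect (known-variance, scale-1) inverse-variance-weighted
meta-regression of LACE on stratum mean GS-free BMI — the standard
construction for tests that are named but not specified.

**Two-sample MR.** Harmonisation aligns outcome alleles to the exposure
study: swap-matches flip beta and complement EAF; palindromic variants
with min(EAF, 1−EAF) > 0.42 in either study are dropped as ambiguous;
unambiguous palindromic rows are re-flipped if frequencies disagree in
side. The operation is idempotent. Protein→BMI uses the lead (smallest-p)
cis variant inside the ±500 kb window and the first-order Wald ratio
(second-order optional); BMI→protein uses genome-wide-significant BMI
variants outside the window, combined by the inverse-variance-weighted
mean of per-variant Wald ratios — the summary-statistic analogue of
multi-instrument 2SLS. Steiger r² is recovered from the z statistic,
r² = z²/(z²+n−2), values clipped into [0, 1−1e−12] with a warning;
direction is supported when exposure r² exceeds outcome r² with Fisher-z
p < 0.05. BH FDR is applied within each direction (the correction the
source leaves unnamed), with Bonferroni flags alongside.

**Colocalisation.** Wakefield log-ABFs from betas and SEs (not p+MAF;
both are in the data model but betas/SEs are primary), prior effect SD
W = 0.15 and priors p1 = p2 = 1e−4, p12 = 1e−5 — the cited tool's
quantitative-trait defaults. All sums run in log space (`logsumexp`); the
H3 pair-sum uses log(e^{s1+s2} − e^{s12}) via `expm1`, exact against an
O(m²) configuration enumeration to 1e−9 in the tests, and overflow-safe
to |z| ≈ 1e3.

**Enrichment.** Upper-tail hypergeometric p via the exact survival
function; term sizes restricted to 3–500 universe members (conventional
bounds). The universe defaults to the measured panel; swapping in an
all-annotated universe is the sensitivity mode — overlap counts k are
invariant to the swap, only p-values move.

## Numerical and testing choices

- BH q-values use the standard step-up with monotonicity enforcement,
  checked exactly against a brute-force oracle and statsmodels.
- 2SLS equals the covariance-ratio IV estimate for a single instrument to
  1e−8; F equals the squared t to 1e−10; the curve anchor holds to
  machine precision (≤1e−12 after interpolation).
- Operating-characteristic simulations (2SLS CI coverage over 500
  cohorts, trend/quadratic type-I over 1000 replicates, threshold-truth
  power, Steiger accuracy) run at n = 4000 with reduced variant counts
  (tens rather than 816) at the same target score r² = 0.037 — these
  characteristics depend on the score's variance share, not on how many
  variants compose it; full 816-variant cohorts are used where the score
  itself is the quantity under test.
- The threshold-truth power regime places a causal effect of 0.60 SD
  protein per SD BMI above the median — the top of the genetic effect
  range, the relevant scale for a causal curve.

## What passing tests do and do not show

The generator draws independent variants (no LD, no haplotypes), linear
covariate effects, Gaussian protein noise, and exactly one causal
cis variant per protein. Passing recovery tests therefore demonstrates
the estimators are correct under the stated model; they do not
demonstrate robustness to LD-induced instrument correlation, assay
batch structure beyond a plate label, non-Gaussian protein tails, or
horizontal pleiotropy of score variants — all outside the model by
design. Sample-overlap bias in two-sample MR and plate-normalisation
internals are likewise out of scope.
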