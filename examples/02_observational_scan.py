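"""Observational proteome-wide scan: adjusted per-protein BMI associations.

Each protein (standardized by its SD) is regressed on BMI in SD units
with the full covariate adjustment; BH FDR and Bonferroni flags control
multiplicity across the panel.
"""

import proteomr as pm

params = pm.SimParams(seed=2)
cohort, dosages, truth = pm.simulate_cohort(params)
panel = pm.simulate_proteins(cohort, truth, params, dosages=dosages)
std = pm.standardize_proteins(panel)

res = pm.fit_protein_associations(cohort, std)
sig = res[res["q_fdr"] < 0.05]
print(f"{len(sig)} of {len(res)} proteins associated with BMI at FDR<0.05 "
      f"({(sig['beta'] > 0).sum()} positive / {(sig['beta'] < 0).sum()} "
      "inverse)")
top = res.nsmallest(3, "p")[["protein", "beta", "se", "p"]]
print(top.to_string(index=False))
# beta is the SD change in protein per SD (3.3 kg/m2) higher BMI; the
# strongest synthetic effects reach ~0.55, matching the generator truth.

prof = pm.quintile_profile(cohort, std[top.iloc[0]["protein"]],
                           covariates=("age", "age2", "sex"))
print(prof.table[["quintile", "bmi_mean", "adj_mean"]].round(3)
      .to_string(index=False))
# Adjusted means rising near-linearly across BMI quintiles indicate a
# linear dose-response shape.
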