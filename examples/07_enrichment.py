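"""Hypergeometric over-representation of top BMI-associated proteins.

The selected list (here: proteins passing the Bonferroni threshold in the
observational scan) is tested against a toy gene-set collection with the
measured panel as the universe.
"""

import proteomr as pm

params = pm.SimParams(seed=7, n_proteins=120)
cohort, dosages, truth = pm.simulate_cohort(params)
panel = pm.simulate_proteins(cohort, truth, params, dosages=dosages)
std = pm.standardize_proteins(panel)
res = pm.fit_protein_associations(cohort, std)
selected = list(res.loc[res["bonf_sig"], "protein"])
universe = list(std.columns)
print(f"{len(selected)} Bonferroni-significant proteins of {len(universe)}")

# toy collection: one term enriched in strong positive responders, others
# drawn at random from the panel
strong = list(res.nsmallest(15, "p")["protein"])
import numpy as np
rng = np.random.default_rng(7)
collection = {
    "POSITIVE_RESPONDERS": ("strongest BMI associations", strong),
    "RANDOM_A": ("random set", list(rng.choice(universe, 20, replace=False))),
    "RANDOM_B": ("random set", list(rng.choice(universe, 25, replace=False))),
}
enr = pm.run_enrichment(selected, universe, collection)
print(enr[["term", "k", "K", "p", "q", "significant"]].to_string(index=False))
# Only the constructed responder set should reach q < 0.05: its members
# sit inside the selected list far more often than chance predicts.
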