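import hypothesis
import numpy as np
import pandas as pd
import pytest

import proteomr as pm

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("default")


def weights_frame(truth) -> pd.DataFrame:
    """Score-weight table from the simulation's true variant effects."""
    meta = truth.variants.set_index("variant_id")
    idx = truth.gs_weights_true.index
    return pd.DataFrame({
        "variant_id": idx,
        "effect_allele": meta.loc[idx, "effect_allele"].to_numpy(),
        "weight": truth.gs_weights_true.to_numpy(),
    })


@pytest.fixture(scope="session")
def small_params():
    return pm.SimParams(n_subjects=800, n_variants=60, n_proteins=20,
                        n_reverse=3, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_params):
    return pm.simulate_cohort(small_params)


@pytest.fixture(scope="session")
def small_panel(small_sim, small_params):
    cohort, dosages, truth = small_sim
    return pm.simulate_proteins(cohort, truth, small_params, dosages=dosages)


@pytest.fixture(scope="session")
def small_score(small_sim):
    _, dosages, truth = small_sim
    return pm.build_score(dosages, weights_frame(truth))


def simple_iv_cohort(rng, n=2000, r2=0.037, beta=0.3, bmi_mean=23.9,
                     bmi_sd=3.3):
    """Minimal single-instrument dataset: score, BMI, one protein.

    BMI is normal here (the marginal shape is irrelevant to the estimator
    checks that use this helper); the protein responds linearly with
    standardized effect ``beta``.
    """
    g = rng.normal(0.0, 1.0, n)
    bmi = bmi_mean + bmi_sd * (np.sqrt(r2) * g
                               + np.sqrt(1 - r2) * rng.normal(0, 1, n))
    z = (bmi - bmi.mean()) / bmi.std()
    y = beta * z + np.sqrt(max(1 - beta ** 2, 0.05)) * rng.normal(0, 1, n)
    cohort = pd.DataFrame({"bmi": bmi})
    return cohort, g, y
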