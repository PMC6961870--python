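import numpy as np
import pytest

from csftriage import (
    CSF_SUBSET,
    NOCSF_SUBSET,
    AgeSexCorrector,
    build_pcc_model,
    default_generator_config,
    derive_simulated_csf_profiles,
    fit_dsi_model,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_pipeline():
    """One fully fitted pipeline on the default synthetic cohort: corrected
    cohort, both DSI models, both PCC models and the simulated CSF
    profiles. Session-scoped because the leave-one-out PCC builds dominate
    the suite's runtime."""
    raw = generate_cohort(default_generator_config(seed=1))
    corrector = AgeSexCorrector().fit(raw)
    cohort = corrector.transform(raw)
    return {
        "raw": raw,
        "corrector": corrector,
        "cohort": cohort,
        "dsi_nocsf": fit_dsi_model(cohort, NOCSF_SUBSET),
        "dsi_csf": fit_dsi_model(cohort, CSF_SUBSET),
        "pcc_nocsf": build_pcc_model(cohort, NOCSF_SUBSET),
        "pcc_csf": build_pcc_model(cohort, CSF_SUBSET),
        "profiles": derive_simulated_csf_profiles(cohort),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
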