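import numpy as np
import pytest

import doripk as dk


@pytest.fixture(scope="session")
def study_cohort():
    """Default synthetic cohort reproducing the study design (21 subjects, 9 CRRT)."""
    return dk.generate_cohort(dk.CohortSpec(), rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def base_fit(study_cohort):
    """Base-model (no covariates) fit of the default cohort, shared across tests."""
    return dk.fit_population(study_cohort, dk.BASE_MODEL_SPEC)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
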