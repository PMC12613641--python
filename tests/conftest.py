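import numpy as np
import pytest

from vaptrials import (CohortSpec, GSDesign, calibrate_onset_model,
                       generate_cohort, max_events)


@pytest.fixture(scope="session")
def obf_one_ia_design():
    """One-interim OBF design at the expected-events-optimal fraction."""
    return GSDesign(info_fractions=(0.64, 1.0))


@pytest.fixture(scope="session")
def scenario1_summary(obf_one_ia_design):
    """Scenario-1 (HR 0.79) sized OBF one-interim design."""
    return max_events(obf_one_ia_design, 0.79)


@pytest.fixture(scope="session")
def onset_model():
    """Default two-rate onset model (28-day incidence 15.5%, median 3 d)."""
    return calibrate_onset_model()


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
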