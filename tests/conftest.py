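import numpy as np
import pytest
from hypothesis import settings

from ipdmasim import ScenarioConfig, generate_dataset
from ipdmasim.onestage import aggregate_cells

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def tiny_dataset():
    """K=3 studies, ~15 subjects each, moderate heterogeneity; every
    (study, arm) cell is non-empty with at least one event and one
    non-event (asserted), so all estimators are well defined."""
    scenario = ScenarioConfig(
        n_studies=3,
        total_size=45,
        size_scheme="balanced",
        beta0=-0.3,
        beta1=0.3,
        tau0_sq=0.5,
        tau1_sq=0.5,
        rho=0.3,
        seed=2000,
    )
    data = generate_dataset(scenario)
    n, y, _ = aggregate_cells(data)
    assert np.all(n > 0) and np.all(y > 0) and np.all(y < n)
    return data


@pytest.fixture
def medium_dataset():
    """K=15 studies of ~200 subjects, matching a large balanced design."""
    scenario = ScenarioConfig(
        n_studies=15,
        total_size=3000,
        size_scheme="balanced",
        tau0_sq=0.05,
        tau1_sq=0.05,
        rho=0.0,
        seed=7,
    )
    return generate_dataset(scenario)
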