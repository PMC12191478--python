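import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mrkinet import published
from mrkinet.datamodel import RunConfig
from mrkinet.estimation import fit_network
from mrkinet.network import RateConstants
from mrkinet.synthetic import (NoiseSpec, default_initial_state,
                               generate_network_timecourse)

STUDY_TIMES = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)


@pytest.fixture(scope="session")
def truth_90():
    """Published network rate constants at 90 C."""
    return published.network_k_values(90.0)


@pytest.fixture(scope="session")
def noisefree_tc_90(truth_90):
    """Noise-free model-system timecourse simulated at 90 C."""
    k = RateConstants.from_dict(truth_90, 90.0)
    return generate_network_timecourse(k, default_initial_state(),
                                       STUDY_TIMES, NoiseSpec())


@pytest.fixture(scope="session")
def noisefree_fit_90(noisefree_tc_90):
    """Full 16-start network fit of the noise-free 90 C data (shared:
    this is the expensive parameter-recovery experiment)."""
    return fit_network(noisefree_tc_90, RunConfig(seed=1))


@pytest.fixture
def protein_series():
    return (np.array(published.PROTEIN_TIMECOURSE["times_min"]),
            np.array(published.PROTEIN_TIMECOURSE["values"]))
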