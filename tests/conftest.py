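import numpy as np
import pytest

from cardiocas import (
    CASParameters,
    COHORT_CAS_MEANS,
    ProtocolTiming,
    simulate_rri_trajectory,
)


@pytest.fixture(scope="session")
def protocol():
    return ProtocolTiming()  # 7 min rest + 2 min exercise + 5 min recovery


@pytest.fixture(scope="session")
def ref_params():
    """Cohort-level CAS vector, noiseless."""
    return CASParameters(**COHORT_CAS_MEANS, sigma=0.0)


@pytest.fixture(scope="session")
def ref_params_noisy():
    """Cohort-level CAS vector with 30 ms beat-to-beat noise."""
    return CASParameters(**COHORT_CAS_MEANS, sigma=30.0)


@pytest.fixture(scope="session")
def noiseless_recording(ref_params, protocol):
    return simulate_rri_trajectory(ref_params, protocol, seed=0)


@pytest.fixture(scope="session")
def noisy_recording(ref_params_noisy, protocol):
    return simulate_rri_trajectory(ref_params_noisy, protocol, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
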