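import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from ctiphantom import (AcquisitionConfig, PhantomLayout, make_truth_maps,
                        simulate_dwi)


@pytest.fixture(scope="session")
def default_layout() -> PhantomLayout:
    return PhantomLayout()


@pytest.fixture(scope="session")
def default_truth(default_layout):
    return make_truth_maps(default_layout)


@pytest.fixture(scope="session")
def noiseless_acq() -> AcquisitionConfig:
    return AcquisitionConfig(noise_model="none")


@pytest.fixture(scope="session")
def noiseless_dwi(default_truth, noiseless_acq):
    return simulate_dwi(default_truth, noiseless_acq)


@pytest.fixture(scope="session")
def designed_alpha() -> dict[str, float]:
    return {"electrolyte": 1.0, "gvs1": 0.6, "gvs2": 0.4, "gvs3": 0.2}
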