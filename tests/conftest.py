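import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tgcsim.empc import ControllerConfig
from tgcsim.patient import PatientParams
from tgcsim.sensor import SensorParams

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def default_patient() -> PatientParams:
    return PatientParams()


@pytest.fixture
def perfect_sensor() -> SensorParams:
    """Error-free sensor: identity readout after the run-in."""
    return SensorParams(
        noise_sd_mmol_l=0.0,
        drift_per_h=0.0,
        cal_error_sd=0.0,
        fail_prob_per_24h=0.0,
        init_gain_sd=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def entry_controller(**kw) -> ControllerConfig:
    """Controller locked to 15-min sampling (aligned-schedule experiments)."""
    kw.setdefault("allowed_intervals_min", (15,))
    return ControllerConfig(**kw)
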