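import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from limnogas import DepthProfile, LakeScenario, generate_profile

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def scenario() -> LakeScenario:
    return LakeScenario(seed=42)


@pytest.fixture
def noiseless_scenario() -> LakeScenario:
    return LakeScenario(seed=42, noise_rel=0.0)


@pytest.fixture
def profile(scenario):
    prof, _ = generate_profile(scenario)
    return prof


@pytest.fixture
def step_profile() -> DepthProfile:
    """Hand-built two-layer profile: conductivity step between 3 and 4 m,
    O2 step between 1 and 2 m."""
    depths = [0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 4.5]
    data = pd.DataFrame(
        {
            "cond_uS_cm": [4500.0, 4500.0, 4510.0, 4505.0, 4500.0, 30000.0, 30100.0],
            "DO_mg_L": [3.6, 3.6, 3.6, 0.1, 0.1, 0.1, 0.1],
            "CH4_umol_L": [153.0, 152.0, 155.0, 170.0, 201.0, 540.0, 615.0],
        },
        index=pd.Index(depths, name="depth_m"),
    )
    return DepthProfile(station_id="step", data=data)


@pytest.fixture
def profile_csv(tmp_path, step_profile):
    from limnogas import write_profile

    path = tmp_path / "profile.csv"
    write_profile(step_profile, path)
    return path
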