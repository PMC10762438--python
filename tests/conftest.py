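import numpy as np
import pandas as pd
import pytest

from pamscape.scene import SceneConfig, make_bathymetry, make_call_schedule, make_env_fields


@pytest.fixture(scope="session")
def scene_config():
    """Small, fast scene: coarse grid, three-month window."""
    return SceneConfig(
        seed=42,
        resolution_deg=0.25,
        start_date="2017-02-10",
        end_date="2017-09-30",
    )


@pytest.fixture(scope="session")
def env_fields(scene_config):
    return make_env_fields(scene_config)


@pytest.fixture(scope="session")
def bathymetry(scene_config):
    return make_bathymetry(scene_config)


@pytest.fixture(scope="session")
def schedule(scene_config, env_fields):
    return make_call_schedule(scene_config, env_fields)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def simple_deployment():
    from pamscape.presence import DeploymentSpec

    return DeploymentSpec(
        start=pd.Timestamp("2017-03-01 00:00"),
        end=pd.Timestamp("2017-03-10 23:59:59"),
        duty_on_min=8.0,
    )
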