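import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ptgtwin as pt
from ptgtwin.core_model import PTGParameters

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return pt.load_config()


@pytest.fixture(scope="session")
def default_params(config):
    return PTGParameters.from_config(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def draw_params(config, rng):
    """Random physiological parameter set around the population defaults."""
    return PTGParameters.from_config(
        config,
        k_ca_setpoint=float(rng.uniform(1.0, 1.3)),
        p_opt=float(rng.uniform(1.2, 2.0)),
        gland_size0=float(rng.uniform(0.5, 3.0)),
        d0=float(0.1 * np.exp(rng.normal(0.0, 0.2))),
        p_rate=float(3.7e5 * np.exp(rng.normal(0.0, 0.3))))
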