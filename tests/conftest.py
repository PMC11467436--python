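import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pulsefret as pf
from pulsefret.recipes import config_for_scenario

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def brownian_trace():
    """One Brownian-diffusion photon trace shared by the FCS tests.

    3 s at the default scenario (25 molecules, D = 90 um^2/s, w_xy = 0.3 um,
    aspect ratio 3), theoretical diffusion time 0.25 ms.
    """
    scenario = pf.DiffusionScenario(duration_s=3.0, rng_seed=1)
    stream = pf.simulate_diffusion_trace(scenario)
    return scenario, stream


@pytest.fixture(scope="session")
def static_burst_dataset():
    """A static-efficiency burst dataset (E = 0.5) with matching config."""
    scenario = pf.SimScenario(n_bursts=2500, true_e=0.5, rng_seed=9)
    stream, truth = pf.simulate_burst_dataset(scenario)
    config = config_for_scenario(scenario)
    table, info = pf.analyze_stream(stream, config)
    return scenario, stream, truth, table
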