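import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from mslrl.ddm import DDMParams
from mslrl.rl_models import RLParams
from mslrl.simulate import simulate_run
from mslrl.task_design import default_config, generate_run


@pytest.fixture(scope="session")
def dc_config():
    return default_config("discriminative_choice")


@pytest.fixture(scope="session")
def mr_config():
    return default_config("match_recognition")


@pytest.fixture(scope="session")
def dc_run(dc_config):
    return generate_run(dc_config, seed=101)


@pytest.fixture(scope="session")
def mr_run(mr_config):
    return generate_run(mr_config, seed=202)


@pytest.fixture(scope="session")
def typical_rl():
    return RLParams(model="simple", eta_c=0.4)


@pytest.fixture(scope="session")
def typical_ddm():
    return DDMParams(a=2.4, tau=0.8)


@pytest.fixture(scope="session")
def mr_behaviour(mr_run, typical_rl, typical_ddm):
    """One simulated match-recognition run at typical child parameters."""
    return simulate_run(mr_run, typical_rl, typical_ddm, vmod=2.0, seed=5)


@pytest.fixture(scope="session")
def dc_behaviour(dc_run, typical_rl, typical_ddm):
    return simulate_run(dc_run, typical_rl, typical_ddm, vmod=2.0, seed=6)
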