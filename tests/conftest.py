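import numpy as np
import pytest

from lcnet import default_config, run_sim1, run_sim2, run_sim3, sweep_stickiness


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# Session-scoped simulation results at the reference configurations
# (seed 0, the documented desk-scale defaults); shared by the acceptance
# tests so each simulation runs once per session.

@pytest.fixture(scope="session")
def sim1_results():
    return run_sim1(default_config(1))


@pytest.fixture(scope="session")
def sim2_results():
    return run_sim2(default_config(2))


@pytest.fixture(scope="session")
def sim2_sweep_results():
    return sweep_stickiness(default_config(2), [0.0, 0.5, 1.0, 2.0])


@pytest.fixture(scope="session")
def sim3_results():
    return run_sim3(default_config(3))
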