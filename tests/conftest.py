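import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from callus import ModelParams, nf1_scenario, normal_scenario, run_simulation
from callus.fixtures import TINY_SIM, tiny_domain


@pytest.fixture(scope="session")
def tiny_dom():
    return tiny_domain()


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def small_dom():
    """8x8 domain for matrix-exponential-scale oracles."""
    from callus.geometry import build_domain

    return build_domain({"n_z": 8, "n_r": 8, "cortex_thickness": 0.2,
                         "half_gap": 0.25})


@pytest.fixture(scope="session")
def normal_result(tiny_dom):
    return run_simulation(normal_scenario(), tiny_dom, seed=1, horizon=21,
                          snapshot_days=(7, 21), sim_config=TINY_SIM)


@pytest.fixture(scope="session")
def nf1_result(tiny_dom):
    return run_simulation(nf1_scenario(), tiny_dom, seed=1, horizon=21,
                          snapshot_days=(7, 21), sim_config=TINY_SIM)
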