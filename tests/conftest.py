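import numpy as np
import pandas as pd
import pytest

from nbox import ModelParams, ModelState, RecordScenario, make_records
from nbox.synthetic import DISTAL_BASELINE


@pytest.fixture(scope="session")
def closed_params() -> ModelParams:
    """Default closed-P setup (fixed 2.42 Pmol inventory, U = 0.1 Sv)."""
    return ModelParams(closed_P=True)


@pytest.fixture(scope="session")
def open_params() -> ModelParams:
    """Default open-P setup (W = 2 mol/s, alpha = 0.25, U = 0.1 Sv)."""
    return ModelParams(closed_P=False)


@pytest.fixture(scope="session")
def closed_steady(closed_params):
    from nbox import solve_steady_state

    return solve_steady_state(closed_params)


@pytest.fixture(scope="session")
def open_steady(open_params):
    from nbox import solve_steady_state

    return solve_steady_state(open_params)


@pytest.fixture
def uniform_state(closed_params) -> ModelState:
    return ModelState.default_initial(closed_params, d15N=3.0)


@pytest.fixture(scope="session")
def deep_records():
    return make_records(RecordScenario(environment="deep-margin", seed=11), n_sites=3)


@pytest.fixture(scope="session")
def distal_records():
    scenario = RecordScenario(
        environment="distal", baseline=DISTAL_BASELINE, age_max=90.0, seed=12
    )
    return make_records(scenario, n_sites=2)
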