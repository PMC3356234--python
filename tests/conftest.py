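import warnings

import numpy as np
import pytest

from chondrosim.model_core import ParameterSet, SystemState
from chondrosim.scenarios import (ScenarioSpec, reference_scenario,
                                  run_scenario)


@pytest.fixture(scope="session")
def ref_params() -> ParameterSet:
    return reference_scenario("with_epo").params


@pytest.fixture(scope="session")
def ref_with_epo_traj():
    """Full-resolution 10-day with-EPO reference run (shared)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_scenario(reference_scenario("with_epo"))


@pytest.fixture(scope="session")
def ref_no_epo_traj():
    """Full-resolution 10-day no-EPO reference run (shared)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_scenario(reference_scenario("no_epo"))


@pytest.fixture()
def coarse_spec(ref_params) -> ScenarioSpec:
    """Small, fast scenario for solver-behaviour tests."""
    return ScenarioSpec(name="coarse", params=ref_params, n_nodes=50,
                        r_max=2.5, horizon=48.0, atol=1e-12)


def random_positive_state(rng: np.random.Generator, n: int,
                          t: float = 0.0) -> SystemState:
    y = rng.uniform(0.1, 5.0, size=(10, n))
    y[5] = rng.uniform(10.0, 120.0, size=n)   # healthy density scale
    y[6] = rng.uniform(0.0, 80.0, size=n)
    y[7] = rng.uniform(0.0, 80.0, size=n)
    y[8] = rng.uniform(0.0, 100.0, size=n)
    return SystemState.from_stack(t, y)
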