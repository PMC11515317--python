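import warnings

import numpy as np
import pytest

from sepmed import (
    EstimatorConfig,
    Intervention,
    ScenarioConfig,
    simulate_lgm,
    simulate_mixed,
    simulation_study_lgm_spec,
    simulation_study_mixed_spec,
)

# the estimator warns when S < 10,000; tests use small S deliberately
warnings.filterwarnings("ignore", message="S = ", category=RuntimeWarning)


@pytest.fixture(scope="session")
def mixed_spec():
    return simulation_study_mixed_spec()


@pytest.fixture(scope="session")
def lgm_spec():
    return simulation_study_lgm_spec()


@pytest.fixture(scope="session")
def contrast():
    return Intervention(x_m=0, x_y=1)


@pytest.fixture(scope="session")
def small_mixed_panel(mixed_spec):
    return simulate_mixed(
        mixed_spec, ScenarioConfig(mechanism="mixed", n=200, T=3, seed=11)
    )


@pytest.fixture(scope="session")
def small_lgm_panel(lgm_spec):
    return simulate_lgm(
        lgm_spec, ScenarioConfig(mechanism="lgm", n=300, T=5, seed=12)
    )


def make_config(**kw):
    kw.setdefault("S", 5000)
    kw.setdefault("B", 0)
    kw.setdefault("seed", 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return EstimatorConfig(**kw)


@pytest.fixture
def config_factory():
    return make_config
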