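import numpy as np
import pytest

from kinepath.dynamics import CouplingParams, PendulumParams, PointMassParams
from kinepath.paths import default_layout
from kinepath.synth import ExperimentConfig, default_group_specs, generate_experiment


@pytest.fixture(scope="session")
def pend() -> PendulumParams:
    return PendulumParams()


@pytest.fixture(scope="session")
def pm() -> PointMassParams:
    return PointMassParams()


@pytest.fixture(scope="session")
def coupling() -> CouplingParams:
    return CouplingParams()


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small but complete experiment (forces simulated) shared across tests."""
    cfg = ExperimentConfig(subjects=2, blocks=2, reaches_per_block=6, seed=123)
    return generate_experiment(cfg, specs=default_group_specs())
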