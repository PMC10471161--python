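import warnings

import numpy as np
import pytest
from hypothesis import settings

from m2afc.synthetic import CELL_OVERRIDES, GeneratorConfig, generate_session, generate_unit_population

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

warnings.filterwarnings("ignore", message="Precision loss occurred")


@pytest.fixture(scope="session")
def vehicle_config() -> GeneratorConfig:
    return GeneratorConfig().with_overrides(**CELL_OVERRIDES[("F", "vehicle")])


@pytest.fixture(scope="session")
def small_session(vehicle_config):
    """One vehicle-female session, ~140 trials."""
    return generate_session(vehicle_config, subject_id="f00", seed=11)


@pytest.fixture(scope="session")
def small_population(vehicle_config, small_session):
    """18 units (13 task-locked) on the shared session, with ground truth."""
    cfg = vehicle_config.with_overrides(n_units=18)
    units, truth = generate_unit_population(cfg, small_session, seed=12)
    return units, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
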