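import numpy as np
import pytest

from ecofoot.pipeline import run_bundle
from ecofoot.synthetic import ScenarioSpec, burden_shift_scenario, generate_mrio


@pytest.fixture(scope="session")
def spec():
    """Default desk-scale scenario: 6 regions x 4 sectors."""
    return ScenarioSpec(seed=11)


@pytest.fixture(scope="session")
def accounts_and_satellite(spec):
    return generate_mrio(spec)


@pytest.fixture(scope="session")
def bundle():
    """One seeded burden-shift bundle shared across read-only tests."""
    return burden_shift_scenario(seed=11)


@pytest.fixture(scope="session")
def result(bundle):
    """Full pipeline run on the shared bundle."""
    return run_bundle(bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
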