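import numpy as np
import pytest

from nirsroi.head import make_synthetic_head
from nirsroi.probe import (
    build_high_density_probe,
    build_low_density_probe,
    register_probe,
)


@pytest.fixture(scope="session")
def head():
    """Default 420-mm synthetic head (variable-depth cortex + deep patch)."""
    return make_synthetic_head(420.0)


@pytest.fixture(scope="session")
def shell_head():
    """Constant 15-mm cortical shell, used where analytic depth matters."""
    return make_synthetic_head(420.0, cortical_depth_profile=15.0)


@pytest.fixture(scope="session")
def low_probe():
    return build_low_density_probe()


@pytest.fixture(scope="session")
def high_probe():
    return build_high_density_probe()


@pytest.fixture(scope="session")
def registered_low(low_probe, head):
    return register_probe(low_probe, head)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)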