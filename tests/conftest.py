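import numpy as np
import pytest
from hypothesis import settings

from togglekit import ToggleParams

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def balanced_bistable() -> ToggleParams:
    """Moderate sequestration, balanced: the canonical bistable reference."""
    return ToggleParams(10, 10, 1, 1)


@pytest.fixture(scope="session")
def balanced_monostable() -> ToggleParams:
    """Strong sequestration pushes the same switch to monostability."""
    return ToggleParams(10, 10, 10, 10)


@pytest.fixture(scope="session")
def free_bistable() -> ToggleParams:
    """No competition: the classical Hill-repression toggle."""
    return ToggleParams(10, 10, 0, 0)


@pytest.fixture(scope="session")
def unbalanced_free() -> ToggleParams:
    """Mildly unbalanced switch (a = 1.15 at alpha0 = 10), no competition."""
    return ToggleParams(9.33, 10.72, 0, 0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
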