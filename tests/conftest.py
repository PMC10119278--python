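import numpy as np
import pytest

from igpepi import (
    canonical_parameters,
    endemic_demo_parameters,
    regime_suite,
    sample_ensemble,
)

#: one fixed seed for every randomized fixture in the suite
SEED = 1


@pytest.fixture(scope="session")
def params():
    """Mild-interaction coexistence scenario with the predator disease endemic."""
    return canonical_parameters()


@pytest.fixture(scope="session")
def endemic_params():
    """Canonical scenario with both diseases endemic at coexistence."""
    return endemic_demo_parameters()


@pytest.fixture(scope="session")
def suite():
    """One (parameters, initial state) pair per non-trivial regime."""
    return regime_suite(SEED)


@pytest.fixture(scope="session")
def small_ensemble():
    """64 regime-sampled parameter sets cycling through all eight regimes."""
    return sample_ensemble(SEED, 64)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
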