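import numpy as np
import pytest
from hypothesis import settings

from adaptscan import AcquisitionModel, make_phantom, simulate_scan

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def nodular_small():
    """128x128 nodular phantom shared across read-only tests."""
    return make_phantom("nodular", 128, 128, n_inclusions=8, seed=1)


@pytest.fixture(scope="session")
def noisy_initial(nodular_small):
    """A quick 300 ns initial scan of the small phantom."""
    return simulate_scan(nodular_small, 300e-9, AcquisitionModel(seed=7))
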