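import numpy as np
import pytest

from spectiq.acquisition import AcquisitionConfig, simulate
from spectiq.phantom import build_phantom, desk_spec


@pytest.fixture(scope="session")
def desk_phantom():
    """Standard 32:1 study phantom at the reduced desk resolution."""
    return build_phantom(desk_spec(32.0, 0.20))


@pytest.fixture(scope="session")
def desk_acq():
    return AcquisitionConfig(bin_size=5.5)


@pytest.fixture(scope="session")
def noiseless_projections(desk_phantom, desk_acq):
    """Matched-model data: attenuation + PSF, no scatter, no noise."""
    return simulate(desk_phantom, desk_acq, noise=False, scatter=False)


@pytest.fixture(scope="session")
def noisy_projections(desk_phantom, desk_acq):
    return simulate(desk_phantom, desk_acq, noise=True, scatter=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
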