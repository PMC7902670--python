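import numpy as np
import pytest

from spiralmap import (
    ResolutionRange,
    VolumeGrid,
    build_filterbank,
    decompose_map,
)
from spiralmap.phantoms import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def default_range():
    return ResolutionRange(15.0, 4.0)


@pytest.fixture(scope="session")
def bank64(default_range):
    return build_filterbank(default_range, 1.0, 64)


@pytest.fixture(scope="session")
def noise_phantom():
    """Pure Gaussian noise box with a central spherical mask."""
    return make_phantom(PhantomSpec("noise_only", seed=3))


@pytest.fixture(scope="session")
def noise_bands(noise_phantom, bank64):
    v, _, _ = noise_phantom
    return decompose_map(v, bank64)


@pytest.fixture(scope="session")
def atoms_snr3():
    """Signed Gaussian-atom phantom, B=100 A^2 imposed, SNR 3."""
    return make_phantom(
        PhantomSpec("gaussian_atoms", seed=0, params={"b_factor": 100.0, "snr": 3.0})
    )


@pytest.fixture(scope="session")
def white_noise_volume():
    rng = np.random.default_rng(1)
    return VolumeGrid(rng.normal(size=(64, 64, 64)), 1.0)
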