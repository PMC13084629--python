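import numpy as np
import pytest

from vcdtmm import ideal_absorber, single_layer_stack

# resonance wavenumbers of the packaged eight-band preset
BAND_CENTERS = np.array([500.0, 1000.0, 1500.0, 2000.0, 2500.0, 3000.0, 3500.0, 4000.0])


@pytest.fixture(scope="session")
def full_grid():
    """The default working grid, 200-4500 cm^-1 in 1 cm^-1 steps."""
    return np.arange(200.0, 4500.0 + 0.5, 1.0)


@pytest.fixture(scope="session")
def coarse_grid():
    """Cheap grid for tests that only need qualitative coverage."""
    return np.arange(200.0, 4500.0, 10.0)


@pytest.fixture(scope="session")
def band_centers():
    return BAND_CENTERS.copy()


@pytest.fixture(scope="session")
def preset():
    return ideal_absorber()


@pytest.fixture(scope="session")
def achiral_preset():
    return ideal_absorber(kappa_0=0.0)


@pytest.fixture
def chiral_film_1um(preset):
    return single_layer_stack(preset, 1.0)


def band_center_indices(nu_grid):
    idx = np.searchsorted(nu_grid, BAND_CENTERS)
    assert np.allclose(nu_grid[idx], BAND_CENTERS), "grid must contain the band centers"
    return idx
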