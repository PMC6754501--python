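import numpy as np
import pytest

from simscope.microscope import default_illumination, simulate_raw_set
from simscope.optics import OtfModel
from simscope.phantoms import make_phantom

NA = 1.33
WAVELENGTH_UM = 0.515
PIXEL_UM = 0.08


@pytest.fixture(scope="session")
def otf128():
    return OtfModel(na=NA, em_wavelength=WAVELENGTH_UM, pixel_size=PIXEL_UM,
                    grid_shape=(128, 128))


@pytest.fixture(scope="session")
def otf256():
    return OtfModel(na=NA, em_wavelength=WAVELENGTH_UM, pixel_size=PIXEL_UM,
                    grid_shape=(256, 256))


@pytest.fixture(scope="session")
def dense_beads256():
    """Calibration-style slide: a dense layer of bead clusters."""
    return make_phantom("bead_clusters", (256, 256), seed=3, pixel_size=PIXEL_UM,
                        n_clusters=40, beads_per_cluster=5)


@pytest.fixture(scope="session")
def beads128():
    return make_phantom("bead_clusters", (128, 128), seed=2, pixel_size=PIXEL_UM,
                        n_clusters=15, beads_per_cluster=3)


@pytest.fixture(scope="session")
def illum08(otf256):
    return default_illumination(otf256, k_fraction=0.8, modulation=0.8,
                                start_phases=(1.0, 0.3, -0.5))


@pytest.fixture(scope="session")
def raw_noiseless256(dense_beads256, illum08, otf256):
    return simulate_raw_set(dense_beads256, illum08, otf256, noiseless=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
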