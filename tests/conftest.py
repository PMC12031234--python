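import numpy as np
import pytest

from lsrm.dip import DIPConfig, EarlyStopRule
from lsrm.image_io import ImageSlice
from lsrm.phantom import PhantomSpec, generate_spheroid_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """64x64, 3-slice spheroid phantom with noise and background."""
    spec = PhantomSpec(
        grid_size=64,
        n_slices=3,
        spheroid_diameter_um=0.6 * 635,
        noise_sigma=0.05,
        fluor_amplitude=0.2,
        seed=7,
    )
    return generate_spheroid_phantom(spec)


@pytest.fixture
def fast_dip_config():
    """Tiny network for cheap unit tests (not for quality checks)."""
    return DIPConfig(
        depth=2,
        base_channels=8,
        skip_channels=4,
        input_channels=8,
        iterations_max=40,
        early_stop=EarlyStopRule(window=10, min_delta=1e-5, patience=3),
        seed=0,
    )


@pytest.fixture
def random_slice(rng):
    return ImageSlice.from_array(rng.uniform(0, 1, (32, 32)))
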