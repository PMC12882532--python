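import numpy as np
import pytest

from capsheet.synthetic_data import DiffractionSpec, MicrographSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def worked_region():
    """7×7 region: central 5×5 at intensity 100, 24 border pixels at 0."""
    region = np.zeros((7, 7))
    region[1:6, 1:6] = 100.0
    return region


@pytest.fixture
def clean_disk_spec():
    """One noise-free disk of fixed radius 10 px."""
    return MicrographSpec(image_size=128, n_aggregates=1,
                          radius_range=(10.0, 10.0), background_noise_sd=0.0,
                          seed=11)


@pytest.fixture
def banded_pair_spec():
    """Noise-free diffraction pair with the default mineral band."""
    from capsheet.synthetic_data import DEFAULT_MINERAL_BAND
    return DiffractionSpec(mineral_band=DEFAULT_MINERAL_BAND, seed=5)
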