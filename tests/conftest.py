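import numpy as np
import pytest

from lesionload.cohort import load_reference_cohort
from lesionload.volumetric import default_grid


@pytest.fixture(scope="session")
def cohort():
    """The packaged 50-patient reference cohort."""
    return load_reference_cohort()


@pytest.fixture()
def grid8():
    """A small 8x8x8 isotropic 2 mm grid (0.008 cc voxels)."""
    return default_grid((8, 8, 8), 2.0)


@pytest.fixture()
def grid16():
    return default_grid((16, 16, 16), 2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
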