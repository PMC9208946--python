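import numpy as np
import pytest

from neurofuzz import PhantomSpec, generate_tissue_phantom


@pytest.fixture(scope="session")
def phantom3():
    """64x64 three-class concentric phantom (CSF/GM/WM means 20/120/220, sd 5)."""
    spec = PhantomSpec(shape=(64, 64), tissue_means=(20.0, 120.0, 220.0),
                       tissue_sd=5.0, seed=7)
    image, labels = generate_tissue_phantom(spec)
    return spec, image, labels


@pytest.fixture(scope="session")
def phantom2_noiseless():
    """64x64 two-class noiseless phantom: exactly two intensity values."""
    spec = PhantomSpec(shape=(64, 64), tissue_means=(20.0, 220.0),
                       tissue_sd=0.0, seed=0)
    image, labels = generate_tissue_phantom(spec)
    return spec, image, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
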