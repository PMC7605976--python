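import numpy as np
import pytest

from musclemap import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_clean():
    """Noiseless default phantom: ground truth is exact."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def phantom_noisy():
    """Same geometry with 10 HU additive Gaussian noise."""
    return generate_phantom(PhantomSpec(seed=7, noise_sd_hu=10.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
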