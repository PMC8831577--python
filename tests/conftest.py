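import numpy as np
import pytest

from deepfat import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_clean():
    """Default noise-free phantom with analytic truth."""
    return generate_phantom(PhantomSpec(), seed=42)


@pytest.fixture(scope="session")
def phantom_noisy():
    return generate_phantom(PhantomSpec(noise_sd=10.0), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
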