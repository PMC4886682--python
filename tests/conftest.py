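import numpy as np
import pytest

from pelletmix import ImageSpec, SimParticle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def thirty_particles():
    """10 green-only, 10 red-only, 10 dual particles for rendering fixtures."""
    return (
        [SimParticle(1, 0, 10.0, True, 4.0) for _ in range(10)]
        + [SimParticle(0, 1, 10.0, True, 4.0) for _ in range(10)]
        + [SimParticle(1, 1, 12.0, True, 4.0) for _ in range(10)]
    )


@pytest.fixture
def clean_image_spec():
    """Noise-free rendering spec with default bleed-through."""
    return ImageSpec(width=512, height=512, blob_sigma=4.0, background=50.0, noise_sd=0.0)
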