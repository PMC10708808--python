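import numpy as np
import pytest

from ipseg.synthetic_data import PhantomParams, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom_stack():
    """Factory: n phantom frames + masks as (n,H,W) arrays, seeded."""

    def make(n: int, size: int = 112, seed: int = 0):
        params = PhantomParams(size=size)
        samples = [generate_phantom(seed * 100_003 + i, params)
                   for i in range(n)]
        images = np.stack([s.image.pixels[0] for s in samples]).astype(np.float32)
        masks = np.stack([s.mask for s in samples])
        return images, masks

    return make


@pytest.fixture
def small_segmenter_kwargs():
    """Estimator settings sized for fast unit tests on 56x56 frames."""
    return dict(factors=(1.0,), aspp_rates=(1, 2), feature_channels=16,
                branch_channels=16, pablock_d=16, n_pablocks=1,
                epochs=1, batch_size=4, random_state=0)
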