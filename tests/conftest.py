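import numpy as np
import pytest

from angiokin import phantom
from angiokin.radiomics.preprocess import DiscretizedVolume


@pytest.fixture(scope="session")
def clean_lesion():
    """Noise-free default phantom lesion (series, mask, truth)."""
    return phantom.generate_lesion(phantom.PhantomSpec(noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_lesion():
    return phantom.generate_lesion(phantom.PhantomSpec(noise_sd=2.0, seed=11))


def random_discretized(rng, max_side=6, ng_max=5):
    """A random small discretized image with a random (nonempty) mask."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    levels = rng.integers(1, ng_max + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask.flat[rng.integers(mask.size)] = True
    levels = np.where(mask, levels, 0)
    ng = int(levels.max())
    return DiscretizedVolume(levels, mask, 1.0, ng)
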