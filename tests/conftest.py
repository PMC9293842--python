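import numpy as np
import pytest

from uswnnm import (
    NoiseSpec,
    PhantomSpec,
    make_phantom,
    preset,
)
from uswnnm.surrogate import build_pairs

# deliberately small geometry for unit tests of the iterative denoiser
SMALL_MATCH = dict(patch_size=5, stride=2, window_radius=6, stack_size=8)


@pytest.fixture(scope="session")
def phantom_96():
    return make_phantom(PhantomSpec("layers", (96, 96), seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def layer_specs(n, size=(64, 64), seed0=100):
    return [PhantomSpec("layers", size, seed=seed0 + i) for i in range(n)]


@pytest.fixture(scope="session")
def surrogate_pairs_layers():
    """40 (noisy, tuned-denoised) pairs of 64x64 layer phantoms at sigma 0.1:
    the first 32 are the training set, the last 8 the held-out test set."""
    cfg = preset("tuned", "medium", 0.1)
    noise = NoiseSpec("speckle", 0.1, seed=5)
    return build_pairs(layer_specs(40), noise, cfg, district_tag="layers")


@pytest.fixture(scope="session")
def surrogate_pairs_ellipses():
    """16 training pairs of 64x64 ellipse phantoms at sigma 0.1."""
    cfg = preset("tuned", "medium", 0.1)
    noise = NoiseSpec("speckle", 0.1, seed=5)
    specs = [PhantomSpec("ellipses", (64, 64), seed=300 + i) for i in range(16)]
    return build_pairs(specs, noise, cfg, district_tag="ellipses")
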