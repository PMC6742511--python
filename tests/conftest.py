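import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from synthreg.io import Image2D, RunConfig
from synthreg.synthetic import PhantomSpec, make_pair, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A 48x48 noiseless three-class phantom pair (A, B)."""
    spec = PhantomSpec(shape=(48, 48), noise_std=0.0, bias_amplitude=0.0)
    return make_phantom(spec, 7)


@pytest.fixture(scope="session")
def small_pair():
    """A small deformed pair with landmarks, for fast end-to-end tests."""
    spec = PhantomSpec(shape=(64, 64))
    return make_pair(spec, 10.0, 99, n_landmarks=6, sigma_k=0.5)


@pytest.fixture
def tiny_config():
    """Settings scaled for unit tests: few trees, small label grid."""
    return RunConfig(
        label_radius=2.0,
        label_step=1.0,
        n_trees=8,
        max_outer=2,
        max_inner=6,
        cp_spacing=12.0,
        cp_spacing_mi=24.0,
    )


def ramp_image(n=32, spacing=1.0):
    x = np.arange(n, dtype=float)
    return Image2D(np.tile(x, (n, 1)), spacing=spacing)
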