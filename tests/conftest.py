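import numpy as np
import pytest

from nirvein import phantom as PH


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, evenly lit phantom with ground truth."""
    spec = PH.PhantomSpec(
        height=96, width=96, n_vessels=2, noise_sigma=0.0,
        illumination_gradient=0.0, seed=11,
    )
    return PH.make_vein_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PH.PhantomSpec(height=96, width=96, n_vessels=3, seed=12)
    return PH.make_vein_phantom(spec)


@pytest.fixture(scope="session")
def stereo_pair():
    """Textured constant-disparity pair with ground truth."""
    spec = PH.StereoPhantomSpec(
        base=PH.PhantomSpec(height=64, width=96, seed=5, noise_sigma=0.01),
        disparity=6,
    )
    return PH.make_stereo_pair(spec)
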