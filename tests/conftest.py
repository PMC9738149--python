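import numpy as np
import pytest

from boldvar.synthdata import PhantomSpec, generate_bold_phantom
from boldvar.types import BoldSeries, VoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_series(rng):
    """A positive random 4D series for oracle-equivalence tests."""
    data = 50.0 + 10.0 * rng.random((6, 6, 3, 20))
    return BoldSeries(data, tr_seconds=1.0)


@pytest.fixture
def random_mask(rng):
    data = rng.random((6, 6, 3)) < 0.6
    data[0, 0, 0] = True  # never empty
    data[1, 1, 1] = True
    return VoiMask(data, "placenta")


@pytest.fixture
def sinusoid_phantom():
    """Noise-free uniform-amplitude phantom: a=0.1, 10 full periods, 200 frames."""
    spec = PhantomSpec(
        grid_shape=(12, 12, 3, 200),
        tr_seconds=1.0,
        inflow_period_s=20.0,
        inflow_amplitude=0.1,
        n_patches=0,
        noise_sd=0.0,
        seed=7,
    )
    return generate_bold_phantom(spec)


@pytest.fixture
def textured_phantom():
    """Small noisy multi-patch phantom suitable for registration tests."""
    spec = PhantomSpec(
        grid_shape=(24, 24, 3, 10),
        n_patches=6,
        patch_amplitude_spread=0.5,
        inflow_amplitude=0.05,
        noise_sd=1.0,
        seed=5,
    )
    return generate_bold_phantom(spec)
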