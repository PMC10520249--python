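import numpy as np
import pytest

from dtienhance.gradients import GradientScheme
from dtienhance.phantom import PhantomSpec, build_phantom, make_dense_scheme


@pytest.fixture(scope="session")
def dense_scheme() -> GradientScheme:
    """90-direction single-shell scheme with one b0, the phantom default."""
    return make_dense_scheme(n=90, bval=1000.0, n_b0=1, seed=0)


@pytest.fixture(scope="session")
def phantom32():
    """Desk-scale 32^3 phantom subject."""
    return build_phantom(PhantomSpec(grid_shape=(32, 32, 32), seed=1))


@pytest.fixture(scope="session")
def phantom24():
    """Smaller phantom for harness-level tests."""
    return build_phantom(PhantomSpec(grid_shape=(24, 24, 24), seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
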