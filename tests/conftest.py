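import numpy as np
import pytest

from aninet import SkullShapeParams, generate_skull


@pytest.fixture(scope="session")
def posed_skull():
    """One synthetic skull in an arbitrary rigid pose."""
    return generate_skull(SkullShapeParams(seed=7, n_points=2000))


@pytest.fixture(scope="session")
def canonical_skull():
    """A noise-free skull in its generation frame (no rigid pose)."""
    return generate_skull(
        SkullShapeParams(seed=11, n_points=2000, noise_sd=0.0, rigid_pose=False)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
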