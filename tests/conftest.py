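import numpy as np
import pytest

from nucleomech import simkit


@pytest.fixture(scope="session")
def ellipsoid_stack():
    """One noisy ellipsoidal nucleus (a=b=5, c=3 um) at the default 0.3 um z-step."""
    stack, truth = simkit.gen_nucleus_stack(
        semi_axes=(5.0, 5.0, 3.0), voxel_xy=0.1, z_step=0.3, noise_sd=2.0, seed=11
    )
    return stack, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
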