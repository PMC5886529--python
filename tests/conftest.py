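import numpy as np
import pytest
from hypothesis import settings

from numreach.simulator import BlockDesign, ModelParams, simulate_block

# property tests must be reproducible run to run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_block():
    """A small reusable threshold-free block (3 ratios x 60 trials)."""
    params = ModelParams(omega=0.17, d=0.06, w=16.0)
    design = BlockDesign(ratios=(0.1, 0.5, 0.9), trials_per_ratio=60)
    return simulate_block(params, design, seed=42)
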