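import numpy as np
import pytest
from hypothesis import settings

import blockart as ba

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_grid():
    return ba.build_grid(16)


@pytest.fixture(scope="session")
def small_system(small_grid):
    """Limited-angle system small enough for dense oracles: n=16, pkt=20."""
    geometry = ba.make_one_by_one(20)
    A = ba.build_system(geometry, small_grid)
    truth = ba.rasterize(ba.phantom_f1(), small_grid)
    b = ba.forward_project(A, truth)
    return A, b, truth, geometry


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
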