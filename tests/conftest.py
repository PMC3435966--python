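import numpy as np
import pytest

import tpscolor as tc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def checker24():
    return tc.checker_24()


@pytest.fixture
def random_controls(rng):
    """A well-conditioned random 24-point control set on [0, 255]^3."""
    P = rng.uniform(0, 255, (24, 3))
    V = rng.uniform(0, 255, (24, 3))
    ids = tuple(f"p{i:02d}" for i in range(24))
    return tc.ControlPointSet(P, V, ids)


@pytest.fixture
def tungsten_scene():
    """Noiseless tungsten/camera-A synthetic chart scene."""
    spec = tc.preset_conditions(seed=7)["T/A"]
    return tc.render_checker(tc.checker_24(), spec, patch_px=8)
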