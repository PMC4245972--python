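import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ebase import make_aform_duplex, make_register_shift
from ebase.geometry import ScalingParams


@pytest.fixture(scope="session")
def params():
    return ScalingParams()


@pytest.fixture(scope="session")
def duplex_gggg():
    return make_aform_duplex("GGGG")


@pytest.fixture(scope="session")
def duplex_shift1():
    return make_register_shift("GGGG", 1)


@pytest.fixture(scope="session")
def duplex_12nt():
    return make_aform_duplex("GCGAUC")


@pytest.fixture
def random_rigid_motion():
    """Deterministic random proper rotation + translation factory."""
    def factory(seed):
        rng = np.random.default_rng(seed)
        rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
        trans = rng.normal(0, 20, 3)
        return rot, trans
    return factory
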