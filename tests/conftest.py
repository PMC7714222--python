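import numpy as np
import pytest

from dgfold.fixtures import make_alpha_beta_target, make_helix
from dgfold.geometry import CaTrace, InternalCoords, internal_to_cartesian


@pytest.fixture(scope="session")
def alpha_beta_target():
    """The synthetic 68-residue α/β study target (trace, ss)."""
    return make_alpha_beta_target(0)


@pytest.fixture(scope="session")
def helix30():
    return make_helix(30)


def random_chain(rng, L, bond=3.8):
    """A random valid chain via internal coordinates."""
    ic = InternalCoords(
        np.full(L - 1, bond),
        rng.uniform(20.0, 160.0, L - 2),
        rng.uniform(-179.9, 180.0, L - 3),
    )
    return internal_to_cartesian(ic)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
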