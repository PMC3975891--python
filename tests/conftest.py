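import numpy as np
import pytest

from ionid.config import RunConfig
from ionid.fixtures import CANONICAL_SPECS, make_site_fixture


@pytest.fixture()
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def canonical_bundles():
    """One noise-free canonical fixture per supported element (seed 11)."""
    return {el: make_site_fixture(spec, seed=11) for el, spec in CANONICAL_SPECS.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_rotation(rng):
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
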