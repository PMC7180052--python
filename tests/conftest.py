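import numpy as np
import pytest

from tractshift.mesh import build_icosphere


@pytest.fixture(scope="session")
def sphere2():
    """Level-2 icosphere (162 vertices), radius 100 mm."""
    return build_icosphere(2, 100.0)


@pytest.fixture(scope="session")
def sphere3():
    """Level-3 icosphere (642 vertices), radius 100 mm."""
    return build_icosphere(3, 100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
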