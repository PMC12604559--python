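import numpy as np
import pytest

import palpsim as ps


@pytest.fixture(scope="session")
def phantoms():
    return {s: ps.standard_phantom(s) for s in ("circle", "rectangle", "horseshoe")}


@pytest.fixture(scope="session")
def circle(phantoms):
    return phantoms["circle"]


@pytest.fixture(scope="session")
def fine_grid(circle):
    return ps.make_grid(circle.spec.workspace_extent, 50)


@pytest.fixture(scope="session")
def coarse_grid(circle):
    return ps.make_grid(circle.spec.workspace_extent, 5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
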