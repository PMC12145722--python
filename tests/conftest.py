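import numpy as np
import pytest

from subfrax.phantom import (
    DEFAULT_ANATOMY,
    DEFAULT_GRID,
    SMOKE_ANATOMY,
    SMOKE_GRID,
    build_phantom,
)


@pytest.fixture(scope="session")
def default_phantom():
    """Default-resolution pelvic phantom (48^3, 2.5 mm)."""
    return build_phantom(DEFAULT_ANATOMY, DEFAULT_GRID, seed=1)


@pytest.fixture(scope="session")
def smoke_phantom():
    """Coarse phantom for fast registration tests (32^3, 3 mm)."""
    return build_phantom(SMOKE_ANATOMY, SMOKE_GRID, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
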