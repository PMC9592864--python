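import numpy as np
import pytest

from ihcquant.io import BinaryMask
from ihcquant.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """256 px phantom used by several unit tests (cheap to render)."""
    spec = PhantomSpec(seed=11, height=256, width=256, blob_scale=24.0,
                       hex_circumradius=24.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def big_phantom():
    """Full-scale 1024 px phantom for the end-to-end checks."""
    return generate_phantom(PhantomSpec(seed=3, height=1024, width=1024))


@pytest.fixture()
def full_roi():
    def _make(shape):
        return BinaryMask(np.ones(shape, dtype=bool), role="roi")

    return _make
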