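import numpy as np
import pytest
from hypothesis import settings

from bbbkit.datatypes import AssayGeometry

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry() -> AssayGeometry:
    """Standard small-solute Transwell geometry."""
    return AssayGeometry()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
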