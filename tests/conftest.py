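import numpy as np
import pytest

from polytomo import build_reference


@pytest.fixture(scope="session")
def ref_fine():
    """Reference at 1 nm/voxel on a 48-voxel box."""
    return build_reference(1.0, 48)


@pytest.fixture(scope="session")
def ref_coarse():
    """Reference at 2 nm/voxel on a 24-voxel box (averaging-scale grid)."""
    return build_reference(2.0, 24)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
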