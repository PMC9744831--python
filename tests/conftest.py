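import numpy as np
import pytest

from leukodrive import make_atlas


@pytest.fixture(scope="session")
def atlas():
    """Work-horse phantom atlas: small enough to be fast, large enough
    that every region (including a >=30-voxel MCP) is well populated."""
    return make_atlas((32, 32, 12))


@pytest.fixture(scope="session")
def scanner_atlas():
    """Atlas matching the reference acquisition geometry: 27 slices of
    5 mm at 0.9375 mm in-plane."""
    return make_atlas((64, 64, 27), spacing=(0.9375, 0.9375), slice_thickness=5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
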