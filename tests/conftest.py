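import numpy as np
import pytest

from spectraits import (
    ParamRanges,
    generate_corpus,
    synthetic_optical_constants,
)


@pytest.fixture(scope="session")
def constants():
    """Full-grid (2000-band) synthetic optical constants."""
    return synthetic_optical_constants(seed=1)


@pytest.fixture(scope="session")
def small_constants():
    """Coarse 50-band constants for fast structural tests."""
    return synthetic_optical_constants(grid=np.linspace(400, 2399, 50), seed=1)


@pytest.fixture(scope="session")
def tiny_corpus(small_constants):
    """60 simulated leaves on the coarse grid."""
    return generate_corpus(ParamRanges(), 60, small_constants, seed=7)
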