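import numpy as np
import pytest

from histohet import Region, generate_csr_pattern


@pytest.fixture
def square_mm() -> Region:
    """1 mm × 1 mm region, full-rectangle ROI."""
    return Region(1000.0, 1000.0)


@pytest.fixture
def csr_pattern(square_mm):
    """A moderately dense spatially random pattern (seeded)."""
    return generate_csr_pattern(300.0, square_mm, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
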