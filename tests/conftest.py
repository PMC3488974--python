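import numpy as np
import pytest
from hypothesis import settings

from drugcombo import ConcentrationGrid, ResponseSurface

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def line3_surface():
    """1-D, 3-level surface with fixed responses (0.2, 0.7, 0.4)."""
    grid = ConcentrationGrid((np.array([0.0, 1.0, 2.0]),))
    return ResponseSurface.from_table(
        grid, np.array([0.2, 0.7, 0.4]), name="line3", normalize=False
    )


@pytest.fixture
def unimodal11_surface():
    """1-D, 11-level unimodal surface peaking at level 7."""
    grid = ConcentrationGrid((np.linspace(0.0, 10.0, 11),))
    values = 1.0 - np.abs(np.arange(11) - 7) / 10.0
    return ResponseSurface.from_table(grid, values, name="unimodal11", normalize=False)
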