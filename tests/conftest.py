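import numpy as np
import pytest

from figseg.geometry import BBox
from figseg.synth import FixtureSpec, generate_figure


@pytest.fixture
def box():
    def make(x0, y0, x1, y1):
        return BBox(x0, y0, x1, y1)

    return make


@pytest.fixture
def clean_2x2():
    """A clean 2x2 fixture: (image, truth)."""
    return generate_figure(FixtureSpec(rows=2, cols=2, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
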