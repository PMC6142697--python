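import numpy as np
import pytest

from briqa import ForegroundMask, PhantomSpec, Slice, generate, ideal_spec


@pytest.fixture
def toy_grid():
    """Deterministic 8x8 slice with full-rectangle foreground interior."""
    rng = np.random.default_rng(42)
    pixels = rng.uniform(0.0, 1.0, (8, 8))
    pixels[0, 0] = 0.0  # pin the rescale anchors
    pixels[7, 7] = 1.0
    mask = np.zeros((8, 8), dtype=bool)
    mask[1:7, 1:7] = True
    return Slice(pixels), ForegroundMask(mask)


@pytest.fixture
def small_phantom():
    spec = PhantomSpec(height=64, width=64, seed=11)
    return generate(spec)


@pytest.fixture
def ideal_phantom():
    return generate(ideal_spec(64, 64, seed=5))
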