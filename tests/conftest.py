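import numpy as np
import pytest

from presscope import (
    PressureFrame,
    default_scene_spec,
    generate_scene,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def supine_scene():
    """One noisy supine phantom with ground truth."""
    return generate_scene(default_scene_spec("supine", seed=42))


@pytest.fixture
def cushion_scene():
    """Supine phantom with the default positioning cushion."""
    return generate_scene(default_scene_spec("supine", with_object=True, seed=42))


@pytest.fixture
def blob_frame():
    """A single isolated noise-free blob at (20, 16), peak 60, sigma 3."""
    r = np.arange(64)[:, None]
    c = np.arange(32)[None, :]
    v = 60.0 * np.exp(-((r - 20) ** 2 + (c - 16) ** 2) / (2 * 3.0**2))
    return PressureFrame(v)
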