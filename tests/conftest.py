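import numpy as np
import pytest

from cropnpp.grids import BAND_NAMES, ReflectanceStack
from cropnpp.scene import SceneConfig, generate_scene


def make_stack(values: dict[str, float | np.ndarray], shape=(4, 4), month=6,
               mask=None) -> ReflectanceStack:
    """Uniform (or explicit-array) stack over all 8 bands."""
    bands = {}
    for bn in BAND_NAMES:
        v = values.get(bn, 0.1)
        bands[bn] = (np.full(shape, float(v)) if np.isscalar(v)
                     else np.asarray(v, float))
    return ReflectanceStack(bands=bands, mask=mask, month=month)


@pytest.fixture(scope="session")
def small_scene():
    """A small clean scene reused by read-only tests."""
    return generate_scene(SceneConfig(shape=(24, 24), seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
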