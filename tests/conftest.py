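import numpy as np
import pytest

from cropdepth import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def unbiased_scene():
    """One flat-background scene with crops clearly above the ground plane."""
    return synthetic.generate_scene(synthetic.SceneSpec(seed=7))


@pytest.fixture
def biased_scene():
    """One scene with a separable background depth drop-off."""
    return synthetic.generate_scene(synthetic.SceneSpec.biased(seed=7))


def random_histogram(rng, bimodal=False):
    """Random 256-bin histogram; optionally two clear Gaussian-ish modes."""
    if bimodal:
        lo = int(rng.integers(20, 90))
        hi = int(rng.integers(150, 235))
        x = np.arange(256)
        h = 800 * np.exp(-0.5 * ((x - lo) / 6.0) ** 2)
        h += 800 * np.exp(-0.5 * ((x - hi) / 6.0) ** 2)
        h += rng.uniform(0, 2, size=256)
        return h
    h = np.zeros(256)
    populated = rng.choice(256, size=int(rng.integers(10, 120)), replace=False)
    h[populated] = rng.integers(1, 500, size=populated.size)
    return h
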