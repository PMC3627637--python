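import numpy as np
import pytest

from lungqct import (
    AttenuationVolume,
    LungSegmentation,
    PhantomSpec,
    ScanPair,
    generate_phantom_pair,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    """Wrap a flat list of HU values into a 1x1xN volume with full mask."""
    grid = np.asarray(values, dtype=float).reshape(1, 1, -1)
    return AttenuationVolume(grid, spacing), LungSegmentation(np.ones_like(grid, bool))


def random_volume(rng, max_side=32, lo=-1024.0, hi=0.0):
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    grid = rng.uniform(lo, hi, size=shape)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[0] = True
    return AttenuationVolume(grid), LungSegmentation(mask)


@pytest.fixture
def identity_pair(rng):
    """Same acquisition used for both phases: all paired measures are fixed points."""
    vol, mask = random_volume(np.random.default_rng(7), max_side=12)
    return ScanPair(insp_volume=vol, insp_mask=mask, exp_volume=vol, exp_mask=mask)


@pytest.fixture(scope="session")
def small_phantom():
    spec = PhantomSpec(shape=(24, 24, 24), f_emph=0.25, f_trap=0.2, seed=42)
    pair, truth = generate_phantom_pair(spec)
    return spec, pair, truth
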