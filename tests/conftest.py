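import numpy as np
import pytest

from jtez.interferometry import demodulate, rephase, synthesize
from jtez.phantom import PhantomSpec, render_jones_field

TEST_GRID = (128, 128)


@pytest.fixture(scope="session")
def default_spec():
    """The default seeded phantom at test scale."""
    return PhantomSpec.default(grid=TEST_GRID)


@pytest.fixture(scope="session")
def single_layer():
    """Single-layer default phantom: composite field + ground truth state."""
    spec = PhantomSpec.default(grid=TEST_GRID, n_layers=1)
    jones, truth = render_jones_field(spec)
    return jones, truth[0]


@pytest.fixture(scope="session")
def recovered_default(default_spec):
    """Recovered (demodulated, rephased) field of the default multi-layer phantom."""
    jones, _ = render_jones_field(default_spec)
    return rephase(demodulate(synthesize(jones, bit_depth=16)))


def random_states(rng: np.random.Generator, n: int, scale: float = 1.0):
    """n random six-component anisotropy draws as an (n, 6) array."""
    return scale * rng.uniform(-1.0, 1.0, size=(n, 6))


def rel_rmse(est: np.ndarray, truth: np.ndarray) -> float:
    return float(np.sqrt(np.mean((est - truth) ** 2)) / np.sqrt(np.mean(truth**2)))
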