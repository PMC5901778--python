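import numpy as np
import pytest

from biofilmca import ColorPattern, Lattice, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return SimulationConfig(L=20, sigma=0.5, rho0=0.05, f=0.5, seed=7)


@pytest.fixture
def random_pattern():
    """Fully occupied 60x60 random 1:1 two-color pattern."""
    g = np.where(np.random.default_rng(1).random((60, 60)) < 0.5, 1, 2)
    return ColorPattern(g)


def full_lattice(L: int, color: int = 1) -> Lattice:
    """Fully occupied single-color lattice (useful to force shoves)."""
    return Lattice(np.full((L, L), color, dtype=np.int8))
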