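import numpy as np
import pytest

from soqy import becke_grid, gaussian_excitation_fixture, uniform_grid


@pytest.fixture(scope="session")
def toy_system():
    """Two-center analytic excitation: hole at origin, electron 4 bohr away."""
    return gaussian_excitation_fixture(separation=4.0, exponent=0.5)


@pytest.fixture(scope="session")
def toy_grid(toy_system):
    return becke_grid(toy_system.centers, level=2)


@pytest.fixture(scope="session")
def dense_uniform_grid():
    """Brute-force reference grid over a box covering the toy system."""
    n = 81
    lo, hi = -6.0, 10.0
    spacing = (hi - lo) / (n - 1)
    return uniform_grid((lo, lo, lo), (n, n, n), spacing)
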