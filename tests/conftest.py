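import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def finite_difference_forces(term, positions, box=None, h=1e-5):
    """Central finite differences of a force term's energy, as -dE/dx."""
    fd = np.zeros_like(positions)
    for i in range(positions.shape[0]):
        for d in range(3):
            pp = positions.copy()
            pp[i, d] += h
            ep, _ = term.energy_and_forces(pp, box)
            pp[i, d] -= 2 * h
            em, _ = term.energy_and_forces(pp, box)
            fd[i, d] = -(ep - em) / (2 * h)
    return fd


def assert_forces_match_fd(term, positions, box=None, h=1e-5, rtol=1e-4):
    _, f = term.energy_and_forces(positions, box)
    fd = finite_difference_forces(term, positions, box, h)
    scale = max(1.0, np.abs(fd).max())
    assert np.abs(f - fd).max() / scale < rtol
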