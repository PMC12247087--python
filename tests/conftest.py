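import numpy as np
import pytest

from chirpendor import HyperfineDistribution, TwoSpinSystem


@pytest.fixture(scope="session")
def system():
    return TwoSpinSystem()  # nu_n = 14.1 MHz, A = 4 MHz


@pytest.fixture(scope="session")
def dist41():
    """Reduced 41-point coupling grid; spectra are insensitive to finer grids."""
    return HyperfineDistribution(n_points=41)


@pytest.fixture(scope="session")
def dist21():
    return HyperfineDistribution(n_points=21)


@pytest.fixture
def rng():
    return np.random.default_rng(20250919)


def rabi_inversion(offsets, nu_eff, duration):
    """Closed-form inversion efficiency of a rectangular pi-area pulse.

    For a rect pulse of effective nutation nu_eff and length t_p = 1/(2 nu_eff)
    (pi pulse): E(x) = sin^2((pi/2) sqrt(1+x^2)) / (1+x^2), x = offset/nu_eff.
    For general durations the flip angle theta = 2 pi nu_eff t_p generalizes to
    E = sin^2((theta/2) sqrt(1+x^2)) / (1+x^2).
    """
    x = np.asarray(offsets, dtype=float) / nu_eff
    theta = 2 * np.pi * nu_eff * duration
    return np.sin((theta / 2) * np.sqrt(1 + x**2)) ** 2 / (1 + x**2)
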