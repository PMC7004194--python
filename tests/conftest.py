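import numpy as np
import pytest

from cuokinetics import (
    MediumSpec,
    ParticleSystem,
    paper_like_params,
    simulate_doped_release,
    simulate_pure_release,
)

HOUR = 3600.0


@pytest.fixture(scope="session")
def times():
    """t = 0 plus 40 log-spaced points from 0.1 h to 250 h, seconds."""
    return np.concatenate(([0.0], np.geomspace(0.1 * HOUR, 250 * HOUR, 40)))


@pytest.fixture(scope="session")
def medium():
    return MediumSpec(amino_acid="valine", c_aa0=5.0, nu=2.0)


@pytest.fixture(scope="session")
def pure_particle():
    return ParticleSystem(d0=10e-9, f_fe0=0.0, mass_conc=0.0125)


@pytest.fixture(scope="session")
def doped_particle():
    return ParticleSystem(d0=10e-9, f_fe0=0.10, mass_conc=0.0125)


@pytest.fixture(scope="session")
def pure_curve(pure_particle, medium, times):
    return simulate_pure_release(pure_particle, medium, paper_like_params(0.0), times)


@pytest.fixture(scope="session")
def doped_curve(doped_particle, medium, times):
    """Noise-free two-step curve for 10 % doping with D = 1e-27 m^2/s."""
    return simulate_doped_release(doped_particle, medium, paper_like_params(0.10), times)
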