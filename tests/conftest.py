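import numpy as np
import pytest

from venosim.device import SalineMedium, default_layout
from venosim.forward import LumenProfile, NoiseModel


@pytest.fixture
def layout():
    return default_layout()


@pytest.fixture
def medium():
    return SalineMedium(conductivity=0.0016)


@pytest.fixture
def no_noise():
    return NoiseModel(relative_sd=0.0)


@pytest.fixture
def uniform_50():
    """Uniform 50 mm**2 lumen covering the full balloon."""
    return LumenProfile.uniform(50.0, 0.0, 60.0, label="uniform50")


def random_smooth_profile(rng, z_start=0.0, z_stop=60.0, grid_step=0.01):
    """Smooth positive CSA profile: constant plus a few random harmonics.

    Returns both the sampled profile and the underlying callable so
    oracles can re-evaluate it independently of the stored grid.
    """
    base = rng.uniform(20.0, 150.0)
    n_harm = rng.integers(1, 4)
    amps = rng.uniform(0.05, 0.25, size=n_harm) * base
    freqs = rng.uniform(0.02, 0.15, size=n_harm)   # cycles per mm
    phases = rng.uniform(0, 2 * np.pi, size=n_harm)

    def f(z):
        z = np.asarray(z, dtype=float)
        out = np.full(z.shape, base)
        for a, fr, ph in zip(amps, freqs, phases):
            out = out + a * np.sin(2 * np.pi * fr * z + ph)
        return out

    z = np.arange(z_start, z_stop + grid_step / 2, grid_step)
    return LumenProfile(z=z, csa=f(z), label="smooth"), f
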