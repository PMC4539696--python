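import numpy as np
import pytest

from simgc.chromatogram import ChannelTrace, SIMRun
from simgc.spectra import FragmentSpectrum, LibraryEntry, SpectralLibrary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spectrum(rng, n_min=2, n_max=8, mass_range=(50, 350)) -> FragmentSpectrum:
    n = int(rng.integers(n_min, n_max + 1))
    masses = rng.choice(np.arange(*mass_range), size=n, replace=False)
    intensities = rng.uniform(10.0, 999.0, size=n)
    intensities[rng.integers(0, n)] = 1000.0
    return FragmentSpectrum.from_pairs(zip(masses, intensities))


def random_library(rng, n=20, ri_range=(700.0, 1500.0)) -> SpectralLibrary:
    entries = []
    for i in range(n):
        ri = float(rng.uniform(*ri_range))
        entries.append(
            LibraryEntry(
                name=f"cmpd_{i:03d}",
                spectrum=random_spectrum(rng),
                ri=ri,
                rt=ri * 0.6,
            )
        )
    return SpectralLibrary(entries)


def gaussian_trace(
    mass=100,
    height=1000.0,
    mu=150.0,
    sigma=2.0,
    dt=0.5,
    t_span=(0.0, 300.0),
    offset=0.0,
    drift=0.0,
    noise=0.0,
    seed=0,
) -> ChannelTrace:
    t = np.arange(t_span[0], t_span[1], dt)
    y = offset + drift * (t - t[0]) + height * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    if noise > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise, t.size)
    return ChannelTrace(mass=mass, times=t, intensities=np.clip(y, 0.0, None))


@pytest.fixture
def small_study():
    """A compact noiseless study shared by pipeline-level tests."""
    from simgc.simulate import make_study

    return make_study(n_targets=3, n_runs=1, seed=7, snr=0.0)
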