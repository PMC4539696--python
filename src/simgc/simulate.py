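"""Synthetic GC-SIM-MS studies with known ground truth.

The generator emulates a spike-in method-development experiment: a small
panel of compounds with known retention and stick spectra, acquired as SIM
channel traces built from Gaussian chromatographic peaks over a drifting
baseline with white detector noise, optionally disturbed by interfering
peaks on shared masses.  Every artifact is reproducible from a single
master seed; per-run and per-channel generators are derived
deterministically so adding a run never reshuffles the others.

Defaults describe the reference study used throughout the test suite:
10 targets x 3 runs, peak width sigma = 2 s, sampling step 0.5 s,
baseline level 50 counts with a drift of 0.02 counts/s, and white noise at
a signal-to-noise ratio of 20 relative to the weakest quantifier apex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .chromatogram import ChannelTrace, SIMRun
from .selection import SIMMethodPlan, TargetDefinition
from .spectra import BASE_PEAK, FragmentSpectrum, LibraryEntry, SpectralLibrary


@dataclass(frozen=True)
class Interferent:
    """An unrelated peak sharing one monitored mass."""

    mass: int
    rt: float
    height: float
    sigma: float = 2.0


@dataclass(frozen=True)
class TargetTruth:
    """True chromatographic parameters of one target."""

    name: str
    rt: float
    sigma: float
    heights: dict[int, float]  # mass -> true apex height


@dataclass
class GroundTruth:
    """Everything needed to recreate or verify a synthetic study."""

    targets: list[TargetTruth]
    baseline_level: float = 50.0
    baseline_drift: float = 0.02  # counts per second
    noise_sigma: float = 0.0  # absolute counts; 0 = noiseless
    interferents: list[Interferent] = field(default_factory=list)
    seed: int = 0
    dt: float = 0.5  # seconds between scans
    time_start: float = 0.0
    time_end: float = 0.0

    def truth_for(self, name: str) -> TargetTruth:
        for t in self.targets:
            if t.name == name:
                return t
        raise KeyError(f"no ground truth for target {name!r}")


# ---------------------------------------------------------------------------
# Library synthesis


def synth_library(
    n_compounds: int,
    seed: int,
    mass_range: tuple[int, int] = (50, 350),
    frags_per_compound_range: tuple[int, int] = (4, 8),
    ri_range: tuple[float, float] = (700.0, 2200.0),
    rt_per_ri: float = 0.6,
    force_collisions: int = 0,
) -> SpectralLibrary:
    """Reproducible random spectral library.

    Fragment masses are drawn without replacement per compound; intensities
    put the base peak at 1000 and the rest uniformly in [30, 900].  RIs
    spread evenly (with jitter) over ``ri_range``; RTs follow linearly at
    ``rt_per_ri`` seconds per RI unit.  ``force_collisions`` copies a
    fragment mass between that many adjacent-RI compound pairs so shared
    masses near coinciding retention exist — the situation penalty-based
    fragment selection is for.
    """
    lo, hi = mass_range
    fmin, fmax = frags_per_compound_range
    if hi - lo + 1 < fmax:
        raise ValueError("mass_range too small for the requested fragment count")
    rng = np.random.default_rng(seed)
    ris = np.sort(rng.uniform(ri_range[0], ri_range[1], size=n_compounds))
    entries: list[LibraryEntry] = []
    for i in range(n_compounds):
        n_frag = int(rng.integers(fmin, fmax + 1))
        masses = rng.choice(np.arange(lo, hi + 1), size=n_frag, replace=False)
        intensities = rng.uniform(30.0, 900.0, size=n_frag)
        intensities[rng.integers(0, n_frag)] = BASE_PEAK
        entries.append(
            LibraryEntry(
                name=f"compound_{i:03d}",
                spectrum=FragmentSpectrum.from_pairs(zip(masses, intensities)),
                ri=float(ris[i]),
                rt=float(ris[i] * rt_per_ri),
            )
        )
    for k in range(min(force_collisions, n_compounds - 1)):
        donor, receiver = entries[k], entries[k + 1]
        shared = donor.spectrum.base_peak_mass
        pairs = list(zip(receiver.spectrum.masses, receiver.spectrum.intensities))
        if shared not in receiver.spectrum.masses:
            pairs[0] = (shared, pairs[0][1])
        entries[k + 1] = replace(
            receiver, spectrum=FragmentSpectrum.from_pairs(pairs)
        )
    return SpectralLibrary(entries)


# ---------------------------------------------------------------------------
# Run synthesis


def _channel_rng(seed: int, run_index: int, mass: int) -> np.random.Generator:
    # Deterministic child stream per (seed, run, channel).
    return np.random.default_rng([seed, run_index, mass])


def synth_run(
    targets: Sequence[TargetDefinition] | SIMMethodPlan,
    truth: GroundTruth,
    run_id: str = "run_00",
    run_index: int = 0,
) -> SIMRun:
    """Simulate one SIM acquisition for the given targets.

    Every monitored channel is ``baseline + drift*t + sum of Gaussian
    peaks + noise``; target peaks land on the channels of their fragment
    masses with the true heights, and interferents add peaks on their own
    mass.  Channels share one scan grid spanning all target RTs (padding
    30 s past the extremes unless the truth fixes the range).
    """
    if isinstance(targets, SIMMethodPlan):
        target_list = [t for w in targets for t in w.targets]
    else:
        target_list = list(targets)
    masses = sorted(
        {m for t in target_list for m in t.masses}
        | {i.mass for i in truth.interferents}
    )
    for t in target_list:
        tt = truth.truth_for(t.name)
        for m in t.masses:
            if m not in tt.heights:
                raise KeyError(
                    f"ground truth for {t.name!r} lacks a height for m/z {m}"
                )

    rts = [truth.truth_for(t.name).rt for t in target_list] + [
        i.rt for i in truth.interferents
    ]
    t0 = truth.time_start if truth.time_end > truth.time_start else min(rts) - 30.0
    t1 = truth.time_end if truth.time_end > truth.time_start else max(rts) + 30.0
    times = np.arange(t0, t1 + truth.dt / 2, truth.dt)

    traces: list[ChannelTrace] = []
    for m in masses:
        y = truth.baseline_level + truth.baseline_drift * (times - times[0])
        for t in target_list:
            tt = truth.truth_for(t.name)
            if m in t.masses:
                h = tt.heights[m]
                y = y + h * np.exp(-0.5 * ((times - tt.rt) / tt.sigma) ** 2)
        for itf in truth.interferents:
            if itf.mass == m:
                y = y + itf.height * np.exp(
                    -0.5 * ((times - itf.rt) / itf.sigma) ** 2
                )
        if truth.noise_sigma > 0:
            rng = _channel_rng(truth.seed, run_index, m)
            y = y + rng.normal(0.0, truth.noise_sigma, size=times.size)
        traces.append(
            ChannelTrace(mass=m, times=times, intensities=np.clip(y, 0.0, None))
        )
    return SIMRun(run_id=run_id, traces=traces, metadata={"seed": truth.seed})


# ---------------------------------------------------------------------------
# Reference study


def make_study(
    n_targets: int = 10,
    n_runs: int = 3,
    seed: int = 0,
    snr: float = 20.0,
    sigma: float = 2.0,
    dt: float = 0.5,
    rt_spacing: float = 40.0,
    n_fragments: int = 4,
    baseline_level: float = 50.0,
    baseline_drift: float = 0.02,
    interferents: Sequence[Interferent] = (),
) -> tuple[SpectralLibrary, list[TargetDefinition], GroundTruth, list[SIMRun]]:
    """The reference synthetic study: a panel of well-separated targets
    acquired in technical-replicate runs.

    Fragment masses are globally unique across the panel (collisions are
    opt-in through ``interferents`` or :func:`synth_library`'s
    ``force_collisions``).  Quantifier heights span 500-5000 counts across
    targets; qualifier heights follow the spectrum's relative intensities.
    ``snr`` fixes the noise sigma as (weakest quantifier height) / snr.
    Replicate runs share the truth; only their noise streams differ.
    """
    rng = np.random.default_rng(seed)
    all_masses = rng.choice(
        np.arange(50, 350), size=n_targets * n_fragments, replace=False
    )
    entries: list[LibraryEntry] = []
    truths: list[TargetTruth] = []
    targets: list[TargetDefinition] = []
    for i in range(n_targets):
        masses = np.sort(all_masses[i * n_fragments : (i + 1) * n_fragments])
        rel = rng.uniform(100.0, 900.0, size=n_fragments)
        rel[rng.integers(0, n_fragments)] = BASE_PEAK
        spectrum = FragmentSpectrum.from_pairs(zip(masses, rel))
        rt = 300.0 + i * rt_spacing + float(rng.uniform(-5.0, 5.0))
        ri = 700.0 + (rt - 300.0) / 0.6
        name = f"target_{i:02d}"
        entry = LibraryEntry(name=name, spectrum=spectrum, rt=rt, ri=ri)
        entries.append(entry)
        quantifier = spectrum.base_peak_mass
        qualifiers = tuple(m for m in spectrum.masses if m != quantifier)
        targets.append(
            TargetDefinition(
                name=name,
                quantifier=quantifier,
                qualifiers=qualifiers,
                reference_spectrum=spectrum,
                rt=rt,
                ri=ri,
            )
        )
        scale = float(rng.uniform(500.0, 5000.0)) / BASE_PEAK
        truths.append(
            TargetTruth(
                name=name,
                rt=rt,
                sigma=sigma,
                heights={int(m): float(a * scale) for m, a in zip(masses, rel)},
            )
        )

    min_qh = min(tr.heights[t.quantifier] for tr, t in zip(truths, targets))
    truth = GroundTruth(
        targets=truths,
        baseline_level=baseline_level,
        baseline_drift=baseline_drift,
        noise_sigma=min_qh / snr if snr > 0 else 0.0,
        interferents=list(interferents),
        seed=seed,
        dt=dt,
    )
    runs = [
        synth_run(targets, truth, run_id=f"run_{r:02d}", run_index=r)
        for r in range(n_runs)
    ]
    return SpectralLibrary(entries), targets, truth, runs
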