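"""Chromatographic preprocessing of SIM channel traces.

Each monitored mass gets an independent treatment: baseline subtraction
(every channel carries its own chemical background level), polynomial
least-squares smoothing, local-maximum peak picking against a robust noise
floor, and a Gaussian shape-quality score (QS) per detected peak.  Peaks of
a target's fragments are then assembled into co-eluting groups anchored on
the quantifier channel: a qualifier only joins a group if its apex lands
within a few scans of the quantifier apex, and qualifiers with a poor peak
shape are kept aside so a distorted EIC cannot corrupt the spectral match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

from .chromatogram import ChannelTrace, SIMRun
from .selection import TargetDefinition
from .spectra import FragmentSpectrum


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing tunables.

    smooth_window / smooth_order:
        Savitzky–Golay window (odd, scans) and polynomial order.
    baseline_window:
        Rolling-minimum span in seconds; must be much wider than a peak.
    noise_k:
        Apex threshold in multiples of the robust noise estimate.
    coelution_tol:
        Maximum apex separation (scans) between a qualifier and the
        quantifier anchor.
    qs_min:
        Gaussian shape-quality floor below which a qualifier's EIC is
        excluded from spectral matching.
    search_halfwidth:
        Half-width (seconds) of the RT search window around the expected
        elution time; quantifier apexes outside it are ignored.
    """

    smooth_window: int = 7
    smooth_order: int = 2
    baseline_window: float = 60.0
    noise_k: float = 3.0
    coelution_tol: int = 2
    qs_min: float = 0.5
    search_halfwidth: float = 4.0

    def __post_init__(self) -> None:
        if self.smooth_window % 2 == 0 or self.smooth_window < 3:
            raise ValueError("smooth_window must be an odd integer >= 3")
        if self.smooth_order >= self.smooth_window:
            raise ValueError("smooth_order must be below smooth_window")
        if not (0.0 <= self.qs_min <= 1.0):
            raise ValueError("qs_min must lie in [0, 1]")
        if self.search_halfwidth <= 0 or self.baseline_window <= 0:
            raise ValueError("windows must be positive")


@dataclass
class GaussianFit:
    mu: float
    sigma: float
    height: float


@dataclass
class PeakCandidate:
    """One detected fragment peak on one channel."""

    mass: int
    apex_index: int
    apex_time: float
    apex_intensity: float
    left: int
    right: int
    auc: float
    qs: float
    gaussian: GaussianFit | None = None

    def __post_init__(self) -> None:
        if not (self.left <= self.apex_index <= self.right):
            raise ValueError("apex index must lie within the peak bounds")
        if self.auc < 0:
            raise ValueError("auc must be non-negative")
        if not (0.0 <= self.qs <= 1.0):
            raise ValueError("qs must lie in [0, 1]")


@dataclass
class PeakGroup:
    """Co-eluting fragment peaks of one target, anchored on the quantifier."""

    consensus_time: float
    members: dict[int, PeakCandidate]
    apex_spectrum: FragmentSpectrum
    auc_spectrum: FragmentSpectrum
    excluded_masses: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# Per-trace operations


def baseline_correct(trace: ChannelTrace, config: PreprocessConfig) -> ChannelTrace:
    """Subtract a per-channel baseline.

    Two passes over blocks of ``baseline_window`` seconds.  First a
    rolling low-quantile envelope (one anchor per block, linearly
    interpolated) gives a provisional baseline; samples rising more than
    three noise sigmas above it are masked as peak territory.  The final
    baseline then interpolates the per-block *median* of the unmasked
    samples — unbiased under symmetric noise, where a raw rolling minimum
    would sit a couple of noise sigmas too low and inflate every apex and
    area estimate.  Corrected intensities are clipped at zero; apexes of
    isolated peaks much narrower than the window are preserved.
    """
    t, y = trace.times, trace.intensities
    if t.size < 3:
        return trace
    span = t[-1] - t[0]
    n_blocks = max(int(math.ceil(span / config.baseline_window)), 1)
    edges = np.linspace(t[0], t[-1], n_blocks + 1)
    blocks = [
        np.flatnonzero((t >= edges[i]) & (t <= edges[i + 1]))
        for i in range(n_blocks)
    ]
    blocks = [b for b in blocks if b.size > 0]

    def interp_anchors(anchors: list[tuple[float, float]]) -> np.ndarray:
        if not anchors:
            return np.full_like(y, float(np.min(y)))
        if len(anchors) == 1:
            return np.full_like(y, anchors[0][1])
        at = np.array([a[0] for a in anchors])
        av = np.array([a[1] for a in anchors])
        return np.interp(t, at, av)

    # Pass 1: low-quantile envelope and peak mask.
    rough = interp_anchors(
        [(float(np.median(t[b])), float(np.quantile(y[b], 0.1))) for b in blocks]
    )
    sigma = noise_level(trace)
    is_peak = (y - rough) > 3.0 * sigma

    # Pass 2: median of baseline (unmasked) samples per block.
    anchors: list[tuple[float, float]] = []
    for b in blocks:
        keep = b[~is_peak[b]]
        if keep.size == 0:
            continue
        anchors.append((float(np.median(t[keep])), float(np.median(y[keep]))))
    base = interp_anchors(anchors)
    return trace.with_intensities(np.clip(y - base, 0.0, None))


def smooth(trace: ChannelTrace, config: PreprocessConfig) -> ChannelTrace:
    """Savitzky–Golay (polynomial least-squares) smoothing.

    Any signal that is locally a polynomial of degree <= ``smooth_order``
    passes through unchanged, so peak apex heights are preserved to first
    order.
    """
    if config.smooth_window > len(trace):
        raise ValueError(
            f"smoothing window {config.smooth_window} exceeds trace length {len(trace)}"
        )
    y = savgol_filter(trace.intensities, config.smooth_window, config.smooth_order)
    return trace.with_intensities(y)


def noise_level(trace: ChannelTrace) -> float:
    """Robust noise scale of a trace from first differences.

    ``1.4826 * median(|diff|) / sqrt(2)`` estimates the white-noise sigma
    of the detrended signal; slow chromatographic structure contributes
    little to successive differences.
    """
    if len(trace) < 3:
        return 0.0
    d = np.diff(trace.intensities)
    return float(1.4826 * np.median(np.abs(d)) / math.sqrt(2.0))


def find_apexes(trace: ChannelTrace, config: PreprocessConfig) -> list[int]:
    """Indices of local maxima exceeding ``noise_k`` times the noise floor.

    Maxima are located on the trace's detection track (the smoothed copy
    when one is attached); the noise floor comes from the unsmoothed
    signal.  Plateau maxima report their center scan.  A flat trace
    yields no apexes.
    """
    y = trace.detection_track
    if y.size < 3 or np.all(y == y[0]):
        return []
    floor = config.noise_k * noise_level(trace)
    idx, props = find_peaks(y, height=max(floor, 0.0), plateau_size=1)
    apexes: list[int] = []
    for i, left, right in zip(idx, props["left_edges"], props["right_edges"]):
        center = (left + right) // 2
        if y[center] > 0:
            apexes.append(int(center))
    return apexes


def _peak_support(
    y: np.ndarray, apex: int, min_half: int = 3, floor_frac: float = 0.01
) -> tuple[int, int]:
    """Local support of a peak: walk outward while the signal decreases,
    stop at a valley or once below ``floor_frac`` of the apex height, but
    keep at least ``min_half`` scans per side (trace permitting) so a
    non-peak-like neighborhood is visible to the shape fit."""
    h = y[apex]
    left = apex
    while left > 0 and y[left - 1] <= y[left] and y[left - 1] > floor_frac * h:
        left -= 1
    right = apex
    n = y.size
    while right < n - 1 and y[right + 1] <= y[right] and y[right + 1] > floor_frac * h:
        right += 1
    left = min(left, max(apex - min_half, 0))
    right = max(right, min(apex + min_half, n - 1))
    return left, right


def _gauss(t: np.ndarray, h: float, mu: float, sigma: float) -> np.ndarray:
    return h * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def gaussian_quality_score(
    trace: ChannelTrace, apex_index: int
) -> tuple[float, GaussianFit | None]:
    """Fit a Gaussian over the peak's local support and score the shape.

    The fit runs on the unsmoothed intensities (so the fitted height is
    free of smoothing attenuation); QS is the coefficient of
    determination of the model against the detection track, clipped to
    ``[0, 1]``.  A failed or degenerate fit scores 0.  The fitted center
    is constrained to within two scans of the apex, so a monotone ramp —
    whose best "Gaussian" would be a far-off tail — cannot score well.
    """
    t, y = trace.times, trace.intensities
    if not (0 <= apex_index < t.size):
        raise IndexError("apex_index outside the trace")
    left, right = _peak_support(trace.detection_track, apex_index)
    # Symmetrize the evaluation window around the apex: a genuine peak has
    # two falling flanks anyway, while a monotone ramp — whose walk-based
    # support is one-sided — must now expose its rising side to the fit
    # and cannot masquerade as a Gaussian flank.
    half = max(apex_index - left, right - apex_index)
    left = max(apex_index - half, 0)
    right = min(apex_index + half, t.size - 1)
    ts, ys = t[left : right + 1], y[left : right + 1]
    if ts.size < 4 or np.all(ys == ys[0]):
        return 0.0, None
    dt = float(np.median(np.diff(ts)))
    span = float(ts[-1] - ts[0])
    h0 = max(float(y[apex_index]), 1e-12)
    mu0 = float(t[apex_index])
    # Width guess from the half-maximum crossing.
    above = ys >= 0.5 * h0
    sigma0 = max(np.count_nonzero(above) * dt / 2.355, dt / 2)
    try:
        popt, _ = curve_fit(
            _gauss,
            ts,
            ys,
            p0=(h0, mu0, sigma0),
            bounds=(
                (h0 * 0.1, mu0 - 2 * dt, dt / 4),
                (h0 * 2.0, mu0 + 2 * dt, max(span, dt)),
            ),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return 0.0, None
    yd = trace.detection_track[left : right + 1]
    resid = yd - _gauss(ts, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((yd - yd.mean()) ** 2))
    if ss_tot <= 0:
        return 0.0, None
    qs = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return qs, GaussianFit(mu=float(popt[1]), sigma=float(popt[2]), height=float(popt[0]))


def peak_candidate(
    trace: ChannelTrace, apex_index: int
) -> PeakCandidate:
    """Assemble a :class:`PeakCandidate` (bounds, AUC, QS, Gaussian fit)
    around an apex on a baseline-corrected trace.

    The apex intensity is the fitted Gaussian height when the shape fit
    succeeds — the maximum-likelihood height under the peak model, less
    noisy than the single apex sample — and the trace value at the apex
    scan otherwise.  The AUC is the trapezoidal area over the peak
    support.
    """
    t, y = trace.times, trace.intensities
    left, right = _peak_support(trace.detection_track, apex_index)
    auc = float(np.trapezoid(y[left : right + 1], t[left : right + 1]))
    qs, fit = gaussian_quality_score(trace, apex_index)
    apex_intensity = fit.height if fit is not None else float(y[apex_index])
    return PeakCandidate(
        mass=trace.mass,
        apex_index=int(apex_index),
        apex_time=float(t[apex_index]),
        apex_intensity=apex_intensity,
        left=int(left),
        right=int(right),
        auc=max(auc, 0.0),
        qs=qs,
        gaussian=fit,
    )


# ---------------------------------------------------------------------------
# Peak grouping


def _nearest_apex(apexes: Sequence[int], anchor: int, tol: int) -> int | None:
    best = None
    for a in apexes:
        if abs(a - anchor) <= tol and (best is None or abs(a - anchor) < abs(best - anchor)):
            best = a
    return best


def build_peak_groups(
    run: SIMRun,
    target: TargetDefinition,
    expected_time: float,
    config: PreprocessConfig,
) -> list[PeakGroup]:
    """Candidate co-eluting peak groups for one target in one run.

    Quantifier apexes within ``expected_time +/- search_halfwidth`` anchor
    the groups.  Each qualifier contributes its nearest apex within
    ``coelution_tol`` scans of the anchor; qualifiers whose peak shape
    scores below ``qs_min`` are listed in ``excluded_masses`` and left out
    of the apex/AUC spectra.  Groups come back sorted by distance from the
    expected time.  The run must already be baseline-corrected and
    smoothed.
    """
    try:
        qtrace = run.get_trace(target.quantifier, near_time=expected_time)
    except KeyError:
        raise KeyError(
            f"run {run.run_id!r}: no channel for quantifier m/z "
            f"{target.quantifier} of target {target.name!r}"
        ) from None

    anchors = [
        i
        for i in find_apexes(qtrace, config)
        if abs(qtrace.times[i] - expected_time) <= config.search_halfwidth
    ]
    qual_traces: dict[int, ChannelTrace] = {}
    qual_apexes: dict[int, list[int]] = {}
    for m in target.qualifiers:
        try:
            tr = run.get_trace(m, near_time=expected_time)
        except KeyError:
            continue
        qual_traces[m] = tr
        qual_apexes[m] = find_apexes(tr, config)

    groups: list[PeakGroup] = []
    for anchor in anchors:
        qcand = peak_candidate(qtrace, anchor)
        members: dict[int, PeakCandidate] = {target.quantifier: qcand}
        excluded: list[int] = []
        for m, tr in qual_traces.items():
            # Same time base within a segment; fall back to time distance
            # if the grids differ.
            if tr.times.size == qtrace.times.size and np.array_equal(
                tr.times, qtrace.times
            ):
                hit = _nearest_apex(qual_apexes[m], anchor, config.coelution_tol)
            else:
                tol_s = config.coelution_tol * max(qtrace.dt, tr.dt)
                hit = None
                t_anchor = qtrace.times[anchor]
                for a in qual_apexes[m]:
                    d = abs(tr.times[a] - t_anchor)
                    if d <= tol_s and (
                        hit is None or d < abs(tr.times[hit] - t_anchor)
                    ):
                        hit = a
            if hit is None:
                continue
            cand = peak_candidate(tr, hit)
            members[m] = cand
            if cand.qs < config.qs_min:
                excluded.append(m)

        kept = [m for m in members if m not in excluded]
        apex_pairs = [(m, members[m].apex_intensity) for m in kept]
        auc_pairs = [(m, members[m].auc) for m in kept]
        groups.append(
            PeakGroup(
                consensus_time=qcand.apex_time,
                members=members,
                apex_spectrum=FragmentSpectrum.from_pairs(apex_pairs),
                auc_spectrum=FragmentSpectrum.from_pairs(auc_pairs),
                excluded_masses=tuple(excluded),
            )
        )
    groups.sort(key=lambda g: abs(g.consensus_time - expected_time))
    return groups


def preprocess_run(run: SIMRun, config: PreprocessConfig) -> SIMRun:
    """Baseline-correct every channel and attach a smoothed detection track.

    The corrected (unsmoothed) intensities stay authoritative for heights
    and areas; the Savitzky-Golay copy only steers apex finding and
    support walks, so smoothing attenuation never biases quantification.
    """
    from dataclasses import replace as _replace

    def one(tr: ChannelTrace) -> ChannelTrace:
        tr = baseline_correct(tr, config)
        if config.smooth_window <= len(tr):
            sm = savgol_filter(
                tr.intensities, config.smooth_window, config.smooth_order
            )
            tr = _replace(tr, smoothed=sm)
        return tr

    return run.map_traces(one)
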