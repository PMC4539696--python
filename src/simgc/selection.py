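"""Quantifier/qualifier fragment selection by penalty optimization.

When designing a SIM method, each target needs a small set of fragments to
monitor: one quantifier plus a few qualifiers.  A good fragment is both
abundant in the target's spectrum and unique among compounds that elute
nearby.  The penalty of fragment j of target i is

    P_ij = (1 / a_ij) * sum_k exp(-|r_i - r_k| / deltaR)

where ``a_ij`` is the fragment's relative intensity, the sum runs over all
fragments of overlapping analytes that share the fragment's nominal mass,
``r`` is the retention index (or RT when no RI is available), and
``deltaR`` sets how quickly a retention mismatch discounts an interferer.
Lower penalty is better: an unshared fragment scores 0, and among shared
fragments higher intensity and larger retention separation win.

Fragments whose relative intensity is below a fraction of the mean of the
target's top-3 intensities are excluded outright — a perfectly unique but
barely detectable fragment is a poor quantifier.

Three input modes mirror typical workflows: *target* (targets provided as
an MSL file, optimized against each other), *library* (a target table
resolved against a background library), and *combined* (targets MSL merged
into the background, then as library mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Literal, Sequence

import numpy as np

from .spectra import (
    FragmentSpectrum,
    LibraryEntry,
    SpectralLibrary,
    TargetRequest,
)

PenaltyFn = Callable[[float, float, Sequence[float], float], float]


@dataclass(frozen=True)
class SelectionConfig:
    """Tunables for fragment selection.

    delta_r:
        RI decay scale of the penalty (RI units).
    ri_tolerance / rt_tolerance:
        Two analytes overlap when their RIs differ by at most
        ``ri_tolerance`` (or RTs by ``rt_tolerance`` seconds when RI is
        unavailable on either side).
    n_default:
        Fragments selected when a request does not say how many
        (one quantifier + three qualifiers).
    min_rel_intensity:
        Relative-intensity floor, as a fraction of the mean of the top-3
        fragment intensities.
    force_optimize:
        Re-optimize even for requests that pinned their masses.
    restrict_to_overlapping:
        Restrict the penalty's sharing set to overlapping analytes
        (default); off compares against the whole library.
    """

    delta_r: float = 10.0
    ri_tolerance: float = 20.0
    rt_tolerance: float = 10.0
    n_default: int = 4
    min_rel_intensity: float = 0.05
    force_optimize: bool = False
    restrict_to_overlapping: bool = True

    def __post_init__(self) -> None:
        for name in ("delta_r", "ri_tolerance", "rt_tolerance", "n_default"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.min_rel_intensity < 1):
            raise ValueError("min_rel_intensity must lie in (0, 1)")


@dataclass(frozen=True)
class PenaltyScore:
    """Penalty of one candidate fragment of one target."""

    target_name: str
    mass: int
    penalty: float
    intensity: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.penalty) and self.penalty >= 0):
            raise ValueError("penalty must be finite and non-negative")


@dataclass
class TargetDefinition:
    """A fully specified SIM target: what to monitor and where to look."""

    name: str
    quantifier: int
    qualifiers: tuple[int, ...]
    reference_spectrum: FragmentSpectrum
    rt: float | None = None
    ri: float | None = None
    window_id: int = 0

    def __post_init__(self) -> None:
        if self.quantifier in self.qualifiers:
            raise ValueError(f"target {self.name!r}: quantifier repeated in qualifiers")
        if self.rt is None and self.ri is None:
            raise ValueError(f"target {self.name!r}: needs an RT or an RI")
        for m in self.masses:
            if m not in self.reference_spectrum.masses:
                raise ValueError(
                    f"target {self.name!r}: reference spectrum lacks m/z {m}"
                )

    @property
    def masses(self) -> tuple[int, ...]:
        return (self.quantifier,) + self.qualifiers


@dataclass(frozen=True)
class SIMWindow:
    start: float
    end: float
    masses: frozenset[int]
    targets: tuple[TargetDefinition, ...]


@dataclass(frozen=True)
class SIMMethodPlan:
    """Ordered, non-overlapping RT windows with their monitored channels."""

    windows: tuple[SIMWindow, ...]

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)


# ---------------------------------------------------------------------------
# Overlap and penalty


def _retention_axis(a: LibraryEntry, b: LibraryEntry) -> tuple[float, float, bool]:
    """Comparable retention values of two entries: RI when both have one,
    otherwise RT.  Returns (value_a, value_b, used_ri)."""
    if a.ri is not None and b.ri is not None:
        return a.ri, b.ri, True
    if a.rt is not None and b.rt is not None:
        return a.rt, b.rt, False
    raise ValueError(
        f"entries {a.name!r} and {b.name!r} share no retention axis (RT or RI)"
    )


def overlapping_analytes(
    entry: LibraryEntry, library: SpectralLibrary, config: SelectionConfig
) -> list[LibraryEntry]:
    """Library entries eluting within tolerance of ``entry`` (RI preferred,
    RT fallback); ``entry`` itself is excluded."""
    if entry.ri is None and entry.rt is None:
        raise ValueError(f"entry {entry.name!r} has neither RT nor RI")
    out: list[LibraryEntry] = []
    for other in library:
        if other is entry:
            continue
        if (
            other.name == entry.name
            and other.ri == entry.ri
            and other.rt == entry.rt
        ):
            continue
        try:
            ra, rb, used_ri = _retention_axis(entry, other)
        except ValueError:
            continue  # no common axis: cannot overlap
        tol = config.ri_tolerance if used_ri else config.rt_tolerance
        if abs(ra - rb) <= tol:
            out.append(other)
    return out


def fragment_penalty(
    intensity: float,
    target_r: float,
    sharer_rs: Sequence[float],
    delta_r: float,
) -> float:
    """Penalty of one fragment given the retention values of every fragment
    (of other analytes) sharing its nominal mass.

    Returns ``(1/a) * sum_k exp(-|r_i - r_k| / delta_r)``; 0 when nothing
    shares the mass.
    """
    if intensity <= 0:
        raise ValueError("fragment intensity must be positive")
    if delta_r <= 0:
        raise ValueError("delta_r must be positive")
    total = sum(math.exp(-abs(target_r - rk) / delta_r) for rk in sharer_rs)
    return total / intensity


def rank_fragments(
    target: LibraryEntry,
    library: SpectralLibrary,
    config: SelectionConfig,
    penalty_fn: PenaltyFn = fragment_penalty,
) -> list[PenaltyScore]:
    """Rank a target's fragments by ascending penalty.

    Fragments below the relative-intensity floor are removed first.
    Survivors are sorted by penalty; ties break by descending intensity,
    then ascending mass.  ``penalty_fn`` may be swapped for a custom
    penalty with the same signature.
    """
    spec = target.spectrum
    top3 = sorted(spec.intensities, reverse=True)[:3]
    floor = config.min_rel_intensity * (sum(top3) / len(top3))
    survivors = [
        (m, a) for m, a in zip(spec.masses, spec.intensities) if a >= floor and a > 0
    ]
    if not survivors:
        raise ValueError(
            f"target {target.name!r}: every fragment fell below the "
            f"relative-intensity floor ({config.min_rel_intensity:g} of the "
            "top-3 mean)"
        )
    if config.restrict_to_overlapping:
        others = overlapping_analytes(target, library, config)
    else:
        others = [e for e in library if e is not target and e.name != target.name]

    scores: list[PenaltyScore] = []
    for m, a in survivors:
        sharer_rs: list[float] = []
        for other in others:
            try:
                r_i, r_k, _ = _retention_axis(target, other)
            except ValueError:
                continue
            for m2 in other.spectrum.masses:
                if m2 == m:
                    sharer_rs.append(r_k)
        r_target = target.ri if target.ri is not None else target.rt
        scores.append(
            PenaltyScore(
                target_name=target.name,
                mass=m,
                penalty=penalty_fn(a, r_target, sharer_rs, config.delta_r),
                intensity=a,
            )
        )
    scores.sort(key=lambda s: (s.penalty, -s.intensity, s.mass))
    return scores


# ---------------------------------------------------------------------------
# Mode dispatch


def _definition_from_entry(
    entry: LibraryEntry, masses: Sequence[int], quantifier: int
) -> TargetDefinition:
    qualifiers = tuple(m for m in masses if m != quantifier)
    return TargetDefinition(
        name=entry.name,
        quantifier=quantifier,
        qualifiers=qualifiers,
        reference_spectrum=entry.spectrum.restrict(list(masses)),
        rt=entry.rt,
        ri=entry.ri,
    )


def _optimized_definition(
    entry: LibraryEntry,
    library: SpectralLibrary,
    n: int,
    pinned_quantifier: int | None,
    config: SelectionConfig,
    penalty_fn: PenaltyFn,
) -> TargetDefinition:
    ranked = rank_fragments(entry, library, config, penalty_fn)
    chosen = [s.mass for s in ranked[:n]]
    if pinned_quantifier is not None:
        if pinned_quantifier not in chosen:
            chosen = [pinned_quantifier] + chosen[: max(n - 1, 0)]
        quantifier = pinned_quantifier
    else:
        quantifier = chosen[0]
    return _definition_from_entry(entry, chosen, quantifier)


def select_fragments(
    requests: Sequence[TargetRequest] | None,
    targets_msl: SpectralLibrary | None = None,
    background: SpectralLibrary | None = None,
    mode: Literal["target", "library", "combined"] = "library",
    config: SelectionConfig | None = None,
    penalty_fn: PenaltyFn = fragment_penalty,
) -> list[TargetDefinition]:
    """Resolve target requests into monitored-fragment definitions.

    * ``target`` mode: targets come from ``targets_msl`` and each is
      optimized against the other targets as background.
    * ``library`` mode: requests resolve against ``background``;
      requests with pinned masses pass through unchanged (unless
      ``force_optimize``), requests without get the top ``n_desired``
      (or ``n_default``) ranked fragments.
    * ``combined`` mode: ``targets_msl`` is merged into ``background``
      (each compound once), then as library mode.

    The first-ranked fragment becomes the quantifier unless the request
    pinned one.
    """
    config = config or SelectionConfig()
    if mode == "target":
        if targets_msl is None:
            raise ValueError("target mode requires a targets MSL library")
        resolving = targets_msl
    elif mode == "library":
        if background is None:
            raise ValueError("library mode requires a background library")
        resolving = background
    elif mode == "combined":
        if targets_msl is None or background is None:
            raise ValueError("combined mode requires both targets MSL and background")
        resolving = targets_msl.merge(background)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if requests is None:
        if targets_msl is None:
            raise ValueError("requests may be omitted only in target/combined mode")
        requests = [TargetRequest(name=e.name) for e in targets_msl]

    by_name = {}
    definitions: list[TargetDefinition] = []
    for req in requests:
        if req.name not in resolving:
            raise KeyError(f"target {req.name!r} not found in the resolving library")
        entry = resolving.get(req.name)
        n = req.n_desired or config.n_default
        if mode == "target":
            optimize = True
        else:
            optimize = config.force_optimize or not req.masses
        if optimize:
            definitions.append(
                _optimized_definition(
                    entry, resolving, n, req.quantifier, config, penalty_fn
                )
            )
        else:
            quantifier = req.quantifier if req.quantifier is not None else req.masses[0]
            definitions.append(_definition_from_entry(entry, req.masses, quantifier))
    return definitions


# ---------------------------------------------------------------------------
# RT window planning


def assign_rt_windows(
    targets: Sequence[TargetDefinition],
    max_channels_per_window: int,
    min_gap: float,
    edge_halfwidth: float = 4.0,
    rt_estimator: Callable[[float], float] | None = None,
) -> SIMMethodPlan:
    """Group targets into SIM acquisition windows, greedily left to right.

    A new window opens when adding the next target (by RT) would exceed
    ``max_channels_per_window`` distinct channels or its RT sits more than
    ``min_gap`` seconds after the window's last target.  Window bounds are
    the midpoints between adjacent windows' edge targets, extended by
    ``edge_halfwidth`` at the extremes.  Targets without an RT use
    ``rt_estimator`` (e.g. an RI calibrator's inverse) on their RI.
    """

    def rt_of(t: TargetDefinition) -> float:
        if t.rt is not None:
            return t.rt
        if rt_estimator is not None and t.ri is not None:
            return float(rt_estimator(t.ri))
        raise ValueError(f"target {t.name!r} has no RT estimate")

    ordered = sorted(targets, key=rt_of)
    groups: list[list[TargetDefinition]] = []
    masses: set[int] = set()
    for t in ordered:
        if len(set(t.masses)) > max_channels_per_window:
            raise ValueError(
                f"target {t.name!r} alone needs {len(set(t.masses))} channels, "
                f"budget is {max_channels_per_window}"
            )
        if groups:
            candidate = masses | set(t.masses)
            gap = rt_of(t) - rt_of(groups[-1][-1])
            if len(candidate) > max_channels_per_window or gap > min_gap:
                groups.append([t])
                masses = set(t.masses)
                continue
            groups[-1].append(t)
            masses = candidate
        else:
            groups.append([t])
            masses = set(t.masses)

    windows: list[SIMWindow] = []
    for i, grp in enumerate(groups):
        first_rt, last_rt = rt_of(grp[0]), rt_of(grp[-1])
        if i == 0:
            start = first_rt - edge_halfwidth
        else:
            start = 0.5 * (rt_of(groups[i - 1][-1]) + first_rt)
        if i == len(groups) - 1:
            end = last_rt + edge_halfwidth
        else:
            end = 0.5 * (last_rt + rt_of(groups[i + 1][0]))
        members = tuple(replace(t, window_id=i) for t in grp)
        windows.append(
            SIMWindow(
                start=start,
                end=end,
                masses=frozenset(m for t in grp for m in t.masses),
                targets=members,
            )
        )
    return SIMMethodPlan(windows=tuple(windows))
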