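"""Stick spectra and spectral libraries.

A SIM acquisition monitors a handful of nominal-mass fragment channels per
analyte, so spectra are represented as sparse "stick" spectra: a short list
of (nominal m/z, relative intensity) pairs.  Libraries associate named
compounds with a spectrum and, optionally, a retention time (RT, seconds)
and/or a retention index (RI, unitless).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

#: Conventional base-peak intensity after normalization.
BASE_PEAK = 1000.0


def _canonical_name(name: str) -> str:
    """Case-folded, whitespace-collapsed form used for name lookups."""
    return " ".join(name.split()).casefold()


@dataclass(frozen=True)
class FragmentSpectrum:
    """An EI stick spectrum: unique ascending nominal masses with
    non-negative relative intensities.

    Parameters
    ----------
    masses:
        Nominal integer m/z values, strictly ascending.
    intensities:
        Relative intensities, same length as ``masses``, all ``>= 0``.
    """

    masses: tuple[int, ...]
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.masses) == 0:
            raise ValueError("spectrum must contain at least one fragment")
        if len(self.masses) != len(self.intensities):
            raise ValueError("masses and intensities differ in length")
        m = np.asarray(self.masses)
        if np.any(np.diff(m) <= 0):
            raise ValueError("masses must be unique and ascending")
        if any(a < 0 for a in self.intensities):
            raise ValueError("intensities must be non-negative")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]]) -> "FragmentSpectrum":
        """Build from (mass, intensity) pairs in any order; masses are
        rounded to nominal integers and must be unique after rounding."""
        rounded = [(int(round(m)), float(a)) for m, a in pairs]
        rounded.sort(key=lambda p: p[0])
        masses = tuple(m for m, _ in rounded)
        if len(set(masses)) != len(masses):
            raise ValueError("duplicate nominal mass after rounding")
        return cls(masses, tuple(a for _, a in rounded))

    @property
    def mass_array(self) -> np.ndarray:
        return np.asarray(self.masses, dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.asarray(self.intensities, dtype=float)

    @property
    def base_peak_mass(self) -> int:
        return self.masses[int(np.argmax(self.intensities))]

    def intensity_of(self, mass: int) -> float:
        """Intensity at a nominal mass, 0 if the mass is absent."""
        try:
            return self.intensities[self.masses.index(mass)]
        except ValueError:
            return 0.0

    def normalized(self, base: float = BASE_PEAK) -> "FragmentSpectrum":
        """Rescale so the base peak equals ``base`` (1000 by convention)."""
        top = max(self.intensities)
        if top <= 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        scale = base / top
        return FragmentSpectrum(self.masses, tuple(a * scale for a in self.intensities))

    def restrict(self, masses: Sequence[int]) -> "FragmentSpectrum":
        """Sub-spectrum over the given nominal masses (order ignored).

        Raises if any requested mass is absent.
        """
        missing = [m for m in masses if m not in self.masses]
        if missing:
            raise KeyError(f"masses not in spectrum: {missing}")
        keep = sorted(set(int(m) for m in masses))
        return FragmentSpectrum(
            tuple(keep), tuple(self.intensity_of(m) for m in keep)
        )

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.masses, self.intensities))

    def __len__(self) -> int:
        return len(self.masses)


@dataclass(frozen=True)
class LibraryEntry:
    """A named compound with its spectrum and optional retention data.

    ``rt`` is stored in seconds (MSL files carry minutes; the reader
    converts).  ``ri`` is the unitless retention index.
    """

    name: str
    spectrum: FragmentSpectrum
    rt: float | None = None
    ri: float | None = None
    cas: str | None = None

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValueError("entry name must be non-empty")
        if self.rt is not None and self.rt <= 0:
            raise ValueError(f"entry {self.name!r}: rt must be positive")


class SpectralLibrary:
    """An ordered collection of library entries with name lookup.

    Names are unique after case-folding and whitespace collapsing.
    """

    def __init__(self, entries: Iterable[LibraryEntry] = ()):  # noqa: D107
        self.entries: list[LibraryEntry] = list(entries)
        self._index: dict[str, int] = {}
        for i, e in enumerate(self.entries):
            key = _canonical_name(e.name)
            if key in self._index:
                raise ValueError(f"duplicate library entry name: {e.name!r}")
            self._index[key] = i

    def get(self, name: str) -> LibraryEntry:
        key = _canonical_name(name)
        if key not in self._index:
            raise KeyError(f"compound not found in library: {name!r}")
        return self.entries[self._index[key]]

    def __contains__(self, name: str) -> bool:
        return _canonical_name(name) in self._index

    def __iter__(self) -> Iterator[LibraryEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def merge(self, other: "SpectralLibrary") -> "SpectralLibrary":
        """Union of two libraries; on a name clash the entry of ``self``
        wins, so each compound appears exactly once."""
        merged = list(self.entries)
        have = set(self._index)
        for e in other:
            if _canonical_name(e.name) not in have:
                merged.append(e)
                have.add(_canonical_name(e.name))
        return SpectralLibrary(merged)


@dataclass(frozen=True)
class TargetRequest:
    """One row of a user target table.

    ``masses`` lists the fragments to monitor (quantifier included) when the
    user pins them; ``n_desired`` asks for that many fragments from the
    optimizer instead; ``quantifier`` pins the quantification mass.
    """

    name: str
    masses: tuple[int, ...] | None = None
    n_desired: int | None = None
    quantifier: int | None = None

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValueError("target name must be non-empty")
        if self.masses is not None:
            if len(set(self.masses)) != len(self.masses):
                raise ValueError(f"target {self.name!r}: duplicate masses")
            if self.quantifier is not None and self.quantifier not in self.masses:
                raise ValueError(
                    f"target {self.name!r}: quantifier {self.quantifier} "
                    "not among its masses"
                )
        if self.n_desired is not None and self.n_desired < 1:
            raise ValueError(f"target {self.name!r}: n_desired must be positive")
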