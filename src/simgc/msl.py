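"""Reader/writer for NIST MSL text libraries.

The MSL dialect accepted here covers the two pair styles seen in NIST and
AMDIS exports: parenthesized ``( 56 152 ) ( 98 148 )`` and bare
``56 152; 98 148;`` pairs, any number per line.  Records start at a
``NAME:`` line; recognized header fields are CASNO/CAS#, RT (minutes),
RI, and ``Num Peaks`` (mandatory before the pair block).

On output, pairs are written parenthesized, five per line, and RT is
written back in minutes.
"""

from __future__ import annotations

import io
import re
from typing import Iterable, TextIO

from .spectra import FragmentSpectrum, LibraryEntry, SpectralLibrary

_PAIR_PAREN = re.compile(r"\(\s*([0-9]+(?:\.[0-9]+)?)\s+([0-9]+(?:\.[0-9]+)?)\s*\)")
_NUM = re.compile(r"[-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?")


class MSLFormatError(ValueError):
    """Raised on malformed MSL input."""


def _parse_pairs(line: str) -> list[tuple[float, float]]:
    if "(" in line:
        return [(float(m), float(a)) for m, a in _PAIR_PAREN.findall(line)]
    nums = _NUM.findall(line)
    if len(nums) % 2 != 0:
        raise MSLFormatError(f"odd number of values in peak line: {line!r}")
    return [(float(nums[i]), float(nums[i + 1])) for i in range(0, len(nums), 2)]


def parse_msl(source: str | TextIO) -> SpectralLibrary:
    """Parse an MSL text stream into a :class:`SpectralLibrary`.

    Intensities are preserved exactly as written (no normalization);
    RT values are converted from minutes to seconds.

    Raises
    ------
    MSLFormatError
        If a record's declared ``Num Peaks`` does not match the number of
        parsed pairs, or peak data appears before any ``NAME:`` line.
    """
    if isinstance(source, str):
        source = io.StringIO(source)

    entries: list[LibraryEntry] = []
    name: str | None = None
    cas: str | None = None
    rt: float | None = None
    ri: float | None = None
    declared: int | None = None
    pairs: list[tuple[float, float]] = []

    def flush() -> None:
        nonlocal name, cas, rt, ri, declared, pairs
        if name is None:
            return
        if declared is None:
            raise MSLFormatError(f"entry {name!r}: missing 'Num Peaks'")
        if len(pairs) != declared:
            raise MSLFormatError(
                f"entry {name!r}: declared {declared} peaks but parsed {len(pairs)}"
            )
        entries.append(
            LibraryEntry(
                name=name,
                cas=cas,
                rt=rt,
                ri=ri,
                spectrum=FragmentSpectrum.from_pairs(pairs),
            )
        )
        name, cas, rt, ri, declared, pairs = None, None, None, None, None, []

    for raw in source:
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("NAME:"):
            flush()
            name = line[5:].strip()
            if not name:
                raise MSLFormatError("empty NAME: field")
        elif upper.startswith(("CASNO:", "CAS#:", "CAS NO:")):
            if name is None:
                raise MSLFormatError(f"field outside of a record: {line!r}")
            cas = line.split(":", 1)[1].strip() or None
        elif upper.startswith("RT:"):
            if name is None:
                raise MSLFormatError(f"field outside of a record: {line!r}")
            rt = float(line.split(":", 1)[1]) * 60.0  # minutes -> seconds
        elif upper.startswith("RI:"):
            if name is None:
                raise MSLFormatError(f"field outside of a record: {line!r}")
            ri = float(line.split(":", 1)[1])
        elif upper.startswith("NUM PEAKS:"):
            if name is None:
                raise MSLFormatError("'Num Peaks' before any NAME:")
            declared = int(line.split(":", 1)[1])
        elif upper.startswith(("COMMENT:", "COMMENTS:", "FORMULA:", "MW:", "SOURCE:")):
            continue  # tolerated but not retained
        else:
            if name is None:
                raise MSLFormatError(f"peak data before any NAME: line: {line!r}")
            if declared is None:
                raise MSLFormatError(f"entry {name!r}: peaks before 'Num Peaks'")
            pairs.extend(_parse_pairs(line))
    flush()
    return SpectralLibrary(entries)


def _fmt(x: float) -> str:
    """Compact numeric formatting: integers bare, floats to 10 significant
    digits (enough for a lossless round trip at the scales involved)."""
    if float(x) == int(x):
        return str(int(x))
    return f"{x:.10g}"


def write_msl(library: SpectralLibrary) -> str:
    """Serialize a library to canonical MSL text.

    ``parse_msl(write_msl(L))`` reproduces every name, CAS, RT, RI, mass and
    intensity of ``L``.
    """
    blocks: list[str] = []
    for e in library:
        lines = [f"NAME: {e.name}"]
        if e.cas is not None:
            lines.append(f"CASNO: {e.cas}")
        if e.rt is not None:
            lines.append(f"RT: {_fmt(e.rt / 60.0)}")
        if e.ri is not None:
            lines.append(f"RI: {_fmt(e.ri)}")
        lines.append(f"Num Peaks: {len(e.spectrum)}")
        pairs = [
            f"({m} {_fmt(a)})"
            for m, a in zip(e.spectrum.masses, e.spectrum.intensities)
        ]
        for i in range(0, len(pairs), 5):
            lines.append(" ".join(pairs[i : i + 5]))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")
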