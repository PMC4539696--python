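"""Retention-index calibration.

A homologous series of RI standards (e.g. FAME or n-alkanes) with known
nominal index values is run alongside the samples; their observed RTs
define a monotone piecewise-linear RT -> RI map, the standard Kovats-style
construction.  The map is exact at every standard and extrapolates beyond
the end standards with the terminal segment slopes.  Because it is strictly
increasing it can be inverted to predict the RT at which a target of known
RI is expected to elute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np


@dataclass(frozen=True)
class RIStandard:
    """One RI standard: nominal index value and observed RT (seconds)."""

    name: str
    ri: float
    rt: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ri) and self.ri > 0):
            raise ValueError(f"standard {self.name!r}: ri must be finite and positive")
        if not (math.isfinite(self.rt) and self.rt > 0):
            raise ValueError(f"standard {self.name!r}: rt must be finite and positive")


class RICalibrator:
    """Piecewise-linear RT <-> RI mapping through calibration knots."""

    def __init__(self, knots: Sequence[tuple[float, float]]):
        knots = sorted((float(rt), float(ri)) for rt, ri in knots)
        if len(knots) < 2:
            raise ValueError("calibration requires at least 2 knots")
        rts = np.array([k[0] for k in knots])
        ris = np.array([k[1] for k in knots])
        if np.any(np.diff(rts) <= 0):
            raise ValueError("knot RTs must be strictly increasing")
        if np.any(np.diff(ris) <= 0):
            raise ValueError("RI must increase strictly with RT")
        self.knots = tuple(knots)
        self._rt = rts
        self._ri = ris

    def _interp(self, x, xp: np.ndarray, fp: np.ndarray):
        x = np.asarray(x, dtype=float)
        y = np.interp(x, xp, fp)
        # np.interp clamps outside the knot range; extend the terminal
        # segments linearly instead.
        lo_slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        hi_slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y = np.where(x < xp[0], fp[0] + (x - xp[0]) * lo_slope, y)
        y = np.where(x > xp[-1], fp[-1] + (x - xp[-1]) * hi_slope, y)
        return float(y) if y.ndim == 0 else y

    def rt_to_ri(self, rt):
        """RI at the given RT(s), by interpolation/terminal extrapolation."""
        return self._interp(rt, self._rt, self._ri)

    def ri_to_rt(self, ri):
        """Inverse map: expected RT for a nominal RI (valid by monotonicity)."""
        return self._interp(ri, self._ri, self._rt)


def fit_ri_model(
    standards: Iterable[RIStandard],
    method: Literal["interpolate", "mean"] = "interpolate",
) -> RICalibrator:
    """Fit the RT -> RI calibrator from observed standards.

    ``interpolate`` (default) places one knot per standard, so the map is
    exact at every observation.  ``mean`` first averages the RTs of
    replicate observations of the same standard (matched by name and
    nominal RI), then interpolates through the averages — useful when the
    standards were injected several times.

    Raises
    ------
    ValueError
        With fewer than 2 (distinct) standards, duplicate RTs, or RI not
        strictly increasing with RT.
    """
    standards = list(standards)
    if method == "mean":
        grouped: dict[tuple[str, float], list[float]] = {}
        for s in standards:
            grouped.setdefault((s.name, s.ri), []).append(s.rt)
        standards = [
            RIStandard(name=name, ri=ri, rt=float(np.mean(rts)))
            for (name, ri), rts in grouped.items()
        ]
    if len(standards) < 2:
        raise ValueError("RI calibration requires at least 2 standards")
    rts = [s.rt for s in standards]
    if len(set(rts)) != len(rts):
        raise ValueError("duplicate RT among RI standards")
    return RICalibrator([(s.rt, s.ri) for s in standards])
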