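"""ANDI/netCDF chromatography-MS reader and writer.

ANDI-MS files store each scan as a sparse list of (mass, intensity) points,
indexed by ``scan_index``/``point_count`` into flat ``mass_values`` and
``intensity_values`` arrays.  For SIM data every scan carries one point per
monitored channel; this module regroups those points into per-channel
:class:`~simgc.chromatogram.ChannelTrace` objects.

The files are classic NetCDF-3, read and written with
:func:`scipy.io.netcdf_file`.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
from scipy.io import netcdf_file

from .chromatogram import ChannelTrace, SIMRun

#: Default channel-joining tolerance in Da; single-quadrupole SIM channels
#: jitter by a fraction of a Dalton around their nominal mass.
DEFAULT_MASS_BIN_TOL = 0.3

_REQUIRED = ("scan_acquisition_time", "mass_values", "intensity_values")


class ANDIFormatError(ValueError):
    """Raised when a netCDF file does not follow ANDI-MS conventions."""


def _scan_offsets(f, n_scans: int, n_points: int) -> np.ndarray:
    """Start offset of every scan (length n_scans + 1)."""
    var = f.variables
    if "scan_index" in var:
        idx = np.asarray(var["scan_index"][:], dtype=np.int64)
        return np.concatenate([idx, [n_points]])
    if "point_count" in var:
        counts = np.asarray(var["point_count"][:], dtype=np.int64)
        return np.concatenate([[0], np.cumsum(counts)])
    raise ANDIFormatError("missing variable scan_index (or point_count)")


def read_sim_run(
    path: str | os.PathLike,
    mass_bin_tol: float = DEFAULT_MASS_BIN_TOL,
    run_id: str | None = None,
) -> SIMRun:
    """Read an ANDI-MS netCDF file into a :class:`SIMRun`.

    Per-scan sparse points are grouped into channels: a point joins an
    existing channel when its mass lies within ``mass_bin_tol`` of that
    channel's nominal mass, otherwise it opens a new channel whose nominal
    mass is the rounded first-seen mass.  A new acquisition segment starts
    whenever the set of monitored channels changes between scans, as happens
    at SIM window boundaries.

    Raises
    ------
    ANDIFormatError
        If a required variable is missing or scan times are not strictly
        increasing.
    """
    if run_id is None:
        run_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    with netcdf_file(os.fspath(path), "r", mmap=False) as f:
        for name in _REQUIRED:
            if name not in f.variables:
                raise ANDIFormatError(f"missing variable {name}")
        times = np.asarray(f.variables["scan_acquisition_time"][:], dtype=float)
        masses = np.asarray(f.variables["mass_values"][:], dtype=float)
        intens = np.asarray(f.variables["intensity_values"][:], dtype=float)
        offsets = _scan_offsets(f, times.size, masses.size)

    if np.any(np.diff(times) <= 0):
        raise ANDIFormatError("scan_acquisition_time is not strictly increasing")
    if offsets[-1] != masses.size or masses.size != intens.size:
        raise ANDIFormatError("scan offsets inconsistent with point arrays")

    # Channel registry: nominal mass of each channel, in creation order.
    nominals: list[int] = []

    def channel_of(m: float) -> int:
        best, best_d = -1, mass_bin_tol
        for nom in nominals:
            d = abs(m - nom)
            if d <= best_d:
                best, best_d = nom, d
        if best >= 0:
            return best
        nom = int(round(m))
        nominals.append(nom)
        return nom

    # Per scan: mapping nominal -> intensity (duplicates within a scan sum).
    scan_channels: list[dict[int, float]] = []
    for s in range(times.size):
        lo, hi = offsets[s], offsets[s + 1]
        chans: dict[int, float] = {}
        for m, a in zip(masses[lo:hi], intens[lo:hi]):
            nom = channel_of(m)
            chans[nom] = chans.get(nom, 0.0) + float(a)
        scan_channels.append(chans)

    # Segment scans by their monitored-channel set; empty scans are skipped
    # and do not break a segment.
    traces: list[ChannelTrace] = []
    seg_id = -1
    current: frozenset[int] | None = None
    seg_times: list[float] = []
    seg_data: dict[int, list[float]] = {}

    def flush_segment() -> None:
        for nom, vals in seg_data.items():
            traces.append(
                ChannelTrace(
                    mass=nom,
                    times=np.asarray(seg_times),
                    intensities=np.asarray(vals),
                    segment_id=seg_id,
                )
            )

    for s, chans in enumerate(scan_channels):
        if not chans:
            continue
        key = frozenset(chans)
        if key != current:
            if current is not None:
                flush_segment()
            seg_id += 1
            current = key
            seg_times = []
            seg_data = {nom: [] for nom in key}
        seg_times.append(float(times[s]))
        for nom in current:
            seg_data[nom].append(chans.get(nom, 0.0))
    if current is not None:
        flush_segment()

    if not traces:
        raise ANDIFormatError("file contains no mass/intensity points")
    return SIMRun(run_id=run_id, traces=traces)


def write_sim_run(run: SIMRun, path: str | os.PathLike) -> None:
    """Write a :class:`SIMRun` as an ANDI-style classic netCDF file.

    Scans are the sorted union of all trace time points; each scan stores
    one (mass, intensity) point per channel sampled at that time, plus the
    summed ``total_intensity``.  ``read_sim_run`` on the written file
    reproduces the run within float precision.
    """
    # Collect points per scan time.  Times from different traces that are
    # bitwise equal share a scan.
    scans: dict[float, list[tuple[float, float]]] = {}
    for tr in run.traces:
        for t, a in zip(tr.times, tr.intensities):
            scans.setdefault(float(t), []).append((float(tr.mass), float(a)))
    times = sorted(scans)

    scan_times = np.asarray(times, dtype=np.float64)
    point_count = np.asarray([len(scans[t]) for t in times], dtype=np.int32)
    scan_index = np.concatenate([[0], np.cumsum(point_count[:-1])]).astype(np.int32)
    mass_values = np.asarray(
        [m for t in times for m, _ in scans[t]], dtype=np.float64
    )
    intensity_values = np.asarray(
        [a for t in times for _, a in scans[t]], dtype=np.float64
    )
    total = np.asarray([sum(a for _, a in scans[t]) for t in times], dtype=np.float64)

    with netcdf_file(os.fspath(path), "w") as f:
        f.history = "simgc synthetic ANDI-MS writer"
        f.createDimension("scan_number", len(times))
        f.createDimension("point_number", int(mass_values.size))

        def var(name: str, data: np.ndarray, dim: str) -> None:
            typecode = "d" if data.dtype == np.float64 else "i"
            v = f.createVariable(name, typecode, (dim,))
            v[:] = data

        var("scan_acquisition_time", scan_times, "scan_number")
        var("scan_index", scan_index, "scan_number")
        var("point_count", point_count, "scan_number")
        var("total_intensity", total, "scan_number")
        var("mass_values", mass_values, "point_number")
        var("intensity_values", intensity_values, "point_number")


def read_total_intensity(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """The file's stored TIC: (scan times, total_intensity)."""
    with netcdf_file(os.fspath(path), "r", mmap=False) as f:
        if "total_intensity" not in f.variables:
            raise ANDIFormatError("missing variable total_intensity")
        t = np.asarray(f.variables["scan_acquisition_time"][:], dtype=float)
        y = np.asarray(f.variables["total_intensity"][:], dtype=float)
    return t, y
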