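"""Delimited-text tables: targets, RI standards, and the results matrix.

All readers accept a path or an open text stream and a configurable
delimiter (comma by default).  Column names are matched case-insensitively
after stripping whitespace.
"""

from __future__ import annotations

import io
import math
import os
import re
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .spectra import TargetRequest

_NAME_COLS = {"name", "target", "analyte", "compound"}
_QF_COLS = {"quantifier", "qf", "quant"}
_N_COLS = {"n", "n_desired", "nfrag", "n_fragments"}
_MASS_COL = re.compile(r"^(qualifier|ql|mass|m)[ _]?\d*$")


def _read_df(source, sep: str | None) -> pd.DataFrame:
    df = pd.read_csv(source, sep=sep, engine="python", skipinitialspace=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _cell_mass(value, row: int, col: str) -> int:
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"row {row}: non-numeric mass {value!r} in column {col!r}"
        ) from None
    if not math.isfinite(x):
        raise ValueError(f"row {row}: non-finite mass in column {col!r}")
    return int(round(x))


def read_target_table(
    source: str | os.PathLike | IO[str], sep: str | None = ","
) -> list[TargetRequest]:
    """Parse a target table into :class:`TargetRequest` records.

    The table needs a name column; optional columns are a quantifier, a
    desired fragment count, and any number of qualifier/mass columns
    (``quantifier``, ``qualifier1`` ..., or ``mass1`` ...).  The quantifier,
    when given, is placed first in the mass list.  Empty cells become absent
    fields.

    Raises
    ------
    ValueError
        On duplicate target names or a non-numeric mass cell (the message
        names the offending row).
    """
    df = _read_df(source, sep)
    name_col = next((c for c in df.columns if c in _NAME_COLS), None)
    if name_col is None:
        raise ValueError("target table must have a name column")
    qf_col = next((c for c in df.columns if c in _QF_COLS), None)
    n_col = next((c for c in df.columns if c in _N_COLS), None)
    mass_cols = [c for c in df.columns if _MASS_COL.match(c)]

    requests: list[TargetRequest] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based, counting the header line
        name = str(row[name_col]).strip()
        key = " ".join(name.split()).casefold()
        if key in seen:
            raise ValueError(f"row {rownum}: duplicate target name {name!r}")
        seen.add(key)

        quantifier = None
        if qf_col is not None and not _isna(row[qf_col]):
            quantifier = _cell_mass(row[qf_col], rownum, qf_col)
        masses: list[int] = [] if quantifier is None else [quantifier]
        for c in mass_cols:
            if _isna(row[c]):
                continue
            m = _cell_mass(row[c], rownum, c)
            if m not in masses:
                masses.append(m)
        n_desired = None
        if n_col is not None and not _isna(row[n_col]):
            n_desired = int(float(row[n_col]))
        requests.append(
            TargetRequest(
                name=name,
                masses=tuple(masses) if masses else None,
                n_desired=n_desired,
                quantifier=quantifier,
            )
        )
    return requests


def _isna(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and not value.strip()


def read_ri_standards(
    source: str | os.PathLike | IO[str], sep: str | None = ","
) -> list["RIStandard"]:
    """Read RI standards (columns: name, ri, rt) with RT in seconds; an
    ``rt_min`` column may be used instead to give RT in minutes."""
    from .ri import RIStandard

    df = _read_df(source, sep)
    if "ri" not in df.columns:
        raise ValueError("RI standards table must have an 'ri' column")
    name_col = next((c for c in df.columns if c in _NAME_COLS), None)
    standards = []
    for i, row in df.iterrows():
        if "rt" in df.columns and not _isna(row["rt"]):
            rt = float(row["rt"])
        elif "rt_min" in df.columns and not _isna(row["rt_min"]):
            rt = float(row["rt_min"]) * 60.0
        else:
            raise ValueError(f"row {int(i) + 2}: missing rt")
        name = str(row[name_col]) if name_col is not None else f"standard_{i}"
        standards.append(RIStandard(name=name, ri=float(row["ri"]), rt=rt))
    return standards


# ---------------------------------------------------------------------------
# Results matrix


_RUN_FIELDS = ("apex", "auc", "score", "rt", "detected")


def results_to_frame(results: Sequence["MatchResult"]) -> pd.DataFrame:
    """Arrange match results as a target x run matrix.

    One row per target; per run a column group ``<run>:apex``, ``:auc``,
    ``:score``, ``:rt``, ``:detected``.  Intensities and RT of undetected
    targets are left missing (never zero-filled); the score is always
    reported.
    """
    targets: list[str] = []
    runs: list[str] = []
    for r in results:
        if r.target not in targets:
            targets.append(r.target)
        if r.run_id not in runs:
            runs.append(r.run_id)

    columns: dict[str, list] = {"target": targets}
    for run in runs:
        for fld in _RUN_FIELDS:
            columns[f"{run}:{fld}"] = [None] * len(targets)
    for r in results:
        i = targets.index(r.target)
        columns[f"{r.run_id}:score"][i] = r.breakdown.overall if r.breakdown else 0.0
        columns[f"{r.run_id}:detected"][i] = bool(r.detected)
        if r.detected:
            columns[f"{r.run_id}:apex"][i] = r.quantifier_apex
            columns[f"{r.run_id}:auc"][i] = r.quantifier_auc
            columns[f"{r.run_id}:rt"][i] = r.attained_rt
    return pd.DataFrame(columns)


def write_results_table(
    results: Sequence["MatchResult"], path: str | os.PathLike | IO[str],
    sep: str = ",",
) -> None:
    """Write the results matrix as delimited text (missing cells empty)."""
    frame = results_to_frame(results)
    frame.to_csv(path, sep=sep, index=False, na_rep="", float_format="%.6g")


def read_results_table(
    source: str | os.PathLike | IO[str], sep: str = ","
) -> pd.DataFrame:
    """Read back a results matrix written by :func:`write_results_table`."""
    return pd.read_csv(source, sep=sep)
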