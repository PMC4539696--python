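"""End-to-end orchestration: runs x targets -> intensity table.

The functional core is :func:`run_study`, which takes in-memory runs and
target definitions and returns one :class:`~simgc.scoring.MatchResult` per
(target, run) cell.  :func:`run_pipeline` wraps it with file I/O: reading
netCDF runs, resolving the target source, fitting the optional RI
calibrator, and writing the delimited results matrix (and EIC plots on
request).  Failures are isolated per cell — a missing quantifier channel
for one target leaves every other cell untouched.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .andi import read_sim_run
from .chromatogram import SIMRun
from .msl import parse_msl
from .preprocess import PeakGroup, PreprocessConfig, build_peak_groups, preprocess_run
from .ri import RICalibrator, fit_ri_model
from .scoring import MatchResult, ScoringConfig, identify_target
from .selection import SelectionConfig, TargetDefinition, select_fragments
from .tables import (
    read_ri_standards,
    read_target_table,
    results_to_frame,
    write_results_table,
)

log = logging.getLogger("simgc")


@dataclass
class PipelineConfig:
    """File-level configuration of a processing session."""

    run_paths: list[str]
    mode: str = "library"  # target | library | combined
    targets_msl: str | None = None
    background_msl: str | None = None
    target_table: str | None = None
    ri_standards: str | None = None
    out_dir: str = "."
    delimiter: str = ","
    plots: bool = False
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)

    def validate(self) -> None:
        for p in self.run_paths:
            if not os.path.exists(p):
                raise FileNotFoundError(f"run file not found: {p}")
        for p in (self.targets_msl, self.background_msl, self.target_table,
                  self.ri_standards):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"input file not found: {p}")


def expected_elution_time(
    target: TargetDefinition, calibrator: RICalibrator | None
) -> float:
    """Expected RT of a target: its own RT, or the calibrator's inverse
    applied to its RI when only an RI is known."""
    if target.rt is not None:
        return target.rt
    if calibrator is not None and target.ri is not None:
        return float(calibrator.ri_to_rt(target.ri))
    raise ValueError(f"target {target.name!r}: no RT and no calibrated RI")


def quantify(group: PeakGroup, quantifier: int) -> tuple[dict, dict, float, float]:
    """Per-fragment apex and AUC intensities of a selected peak group.

    Apex values are the baseline-corrected intensities at the fragment
    apexes; AUCs are trapezoidal areas over each fragment's peak support.
    The quantifier-mass values are returned separately as the recommended
    quantities for relative comparisons across runs.
    """
    apex = {m: c.apex_intensity for m, c in group.members.items()}
    auc = {m: c.auc for m, c in group.members.items()}
    return apex, auc, apex.get(quantifier, 0.0), auc.get(quantifier, 0.0)


def process_one(
    run: SIMRun,
    target: TargetDefinition,
    pre_cfg: PreprocessConfig,
    score_cfg: ScoringConfig,
    calibrator: RICalibrator | None = None,
    preprocessed: bool = True,
) -> MatchResult:
    """Identify and quantify one target in one (preprocessed) run."""
    if not preprocessed:
        run = preprocess_run(run, pre_cfg)
    try:
        expected = expected_elution_time(target, calibrator)
    except ValueError as exc:
        raise ValueError(str(exc)) from None
    try:
        groups = build_peak_groups(run, target, expected, pre_cfg)
    except KeyError as exc:
        log.warning("%s", exc)
        return MatchResult(
            target=target.name, run_id=run.run_id, detected=False,
            reason=str(exc),
        )
    result = identify_target(
        run.run_id, target, groups, score_cfg,
        expected_time=expected, calibrator=calibrator,
    )
    log.info(
        "run=%s target=%s candidates=%d best=%.3f detected=%s%s",
        run.run_id, target.name, len(groups), result.overall, result.detected,
        "" if result.reason is None else f" reason={result.reason!r}",
    )
    return result


def run_study(
    runs: Sequence[SIMRun],
    targets: Sequence[TargetDefinition],
    pre_cfg: PreprocessConfig | None = None,
    score_cfg: ScoringConfig | None = None,
    calibrator: RICalibrator | None = None,
) -> list[MatchResult]:
    """Process every (target, run) cell; the deterministic pipeline core."""
    pre_cfg = pre_cfg or PreprocessConfig()
    score_cfg = score_cfg or ScoringConfig()
    results: list[MatchResult] = []
    for run in runs:
        prepped = preprocess_run(run, pre_cfg)
        for target in targets:
            results.append(
                process_one(prepped, target, pre_cfg, score_cfg, calibrator)
            )
    return results


def resolve_targets(config: PipelineConfig) -> list[TargetDefinition]:
    """Build target definitions from the configured sources and mode."""
    targets_msl = (
        parse_msl(Path(config.targets_msl).read_text())
        if config.targets_msl
        else None
    )
    background = (
        parse_msl(Path(config.background_msl).read_text())
        if config.background_msl
        else None
    )
    requests = (
        read_target_table(config.target_table, sep=config.delimiter)
        if config.target_table
        else None
    )
    return select_fragments(
        requests,
        targets_msl=targets_msl,
        background=background,
        mode=config.mode,
        config=config.selection,
    )


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Full file-to-file processing; returns the results matrix."""
    config.validate()
    targets = resolve_targets(config)

    calibrator = None
    if config.ri_standards:
        calibrator = fit_ri_model(read_ri_standards(config.ri_standards,
                                                    sep=config.delimiter))
    runs = [read_sim_run(p) for p in config.run_paths]
    results = run_study(
        runs, targets, config.preprocess, config.scoring, calibrator
    )

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_results_table(results, out_dir / "results.csv", sep=config.delimiter)
    if config.plots:
        from .plotting import plot_eic

        by_run = {r.run_id: r for r in runs}
        for res in results:
            target = next(t for t in targets if t.name == res.target)
            fig = plot_eic(
                by_run[res.run_id], target, res,
                expected_rt=expected_elution_time(target, calibrator),
            )
            fig.savefig(out_dir / f"eic_{res.run_id}_{res.target}.png", dpi=100)
            import matplotlib.pyplot as plt

            plt.close(fig)
    return results_to_frame(results)


def compute_tic(run: SIMRun) -> tuple[np.ndarray, np.ndarray]:
    """Total ion chromatogram: pointwise channel sum.

    Channels sharing a time base are summed directly; otherwise every
    channel is linearly resampled (zero outside its segment) onto the
    sorted union grid first.
    """
    grids = [tr.times for tr in run.traces]
    same = all(
        g.size == grids[0].size and np.array_equal(g, grids[0]) for g in grids
    )
    if same:
        total = np.sum([tr.intensities for tr in run.traces], axis=0)
        return grids[0].copy(), total
    union = np.unique(np.concatenate(grids))
    total = np.zeros_like(union)
    for tr in run.traces:
        total += np.interp(union, tr.times, tr.intensities, left=0.0, right=0.0)
    return union, total
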