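"""TIC and EIC visualization.

EIC figures show one colored curve per monitored fragment (labeled by
mass), dashed vertical lines at the expected and attained RT, and a
side panel with a pseudo chromatographic peak: the fitted quantifier peak
shape rescaled to each fragment's reference intensity, i.e. what the
channel traces should look like if the detected group truly is the target.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .chromatogram import SIMRun
from .pipeline import compute_tic
from .scoring import MatchResult
from .selection import TargetDefinition


def plot_tic(run: SIMRun, path: str | None = None):
    """Plot the total ion chromatogram of a run; returns the figure."""
    t, y = compute_tic(run)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(t / 60.0, y, lw=0.8)
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("total intensity")
    ax.set_title(f"TIC — {run.run_id}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
    return fig


def plot_eic(
    run: SIMRun,
    target: TargetDefinition,
    match: MatchResult | None = None,
    expected_rt: float | None = None,
    halfwidth: float = 30.0,
    path: str | None = None,
):
    """Plot the EICs of a target's monitored fragments; returns the figure.

    The right panel holds the pseudo peak built from the fitted quantifier
    shape and the target's reference spectrum.  For an undetected target
    only the expected-RT marker is drawn.
    """
    center = expected_rt if expected_rt is not None else (
        match.attained_rt if match is not None and match.attained_rt else
        target.rt
    )
    fig, (ax, ax2) = plt.subplots(
        1, 2, figsize=(10, 3.5), gridspec_kw={"width_ratios": [3, 1]}
    )
    for m in target.masses:
        try:
            tr = run.get_trace(m, near_time=center)
        except KeyError:
            continue
        sel = np.abs(tr.times - center) <= halfwidth
        if not np.any(sel):
            sel = slice(None)
        ax.plot(tr.times[sel], tr.intensities[sel], lw=1.0, label=f"m/z {m}")
    if expected_rt is not None:
        ax.axvline(expected_rt, ls="--", color="gray", label="expected RT")
    if match is not None and match.detected and match.attained_rt is not None:
        ax.axvline(match.attained_rt, ls="--", color="black", label="attained RT")
    ax.set_xlabel("retention time (s)")
    ax.set_ylabel("intensity")
    score = f", score {match.overall:.3f}" if match is not None else ""
    ax.set_title(f"{target.name} — {run.run_id}{score}")
    ax.legend(fontsize=7)

    # Pseudo peak: fitted quantifier shape scaled by reference intensities.
    fit = None
    if match is not None and match.group is not None:
        cand = match.group.members.get(target.quantifier)
        fit = cand.gaussian if cand is not None else None
    if fit is not None:
        tt = np.linspace(fit.mu - 4 * fit.sigma, fit.mu + 4 * fit.sigma, 120)
        ref = target.reference_spectrum.normalized()
        for m in target.masses:
            rel = ref.intensity_of(m) / 1000.0
            ax2.plot(
                tt,
                fit.height * rel * np.exp(-0.5 * ((tt - fit.mu) / fit.sigma) ** 2),
                lw=1.0,
            )
        ax2.set_title("expected EICs", fontsize=8)
    else:
        ax2.set_title("no detection", fontsize=8)
    ax2.set_xlabel("time (s)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
    return fig
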