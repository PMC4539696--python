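# Methods

This note documents the models, estimators, numerical choices and known
limitations of `simgc`. It is written for users who need to judge what the
pipeline's numbers mean and for maintainers who need to know why a given
default was chosen.

## Problem setting

A GC-SIM-MS acquisition monitors, per retention-time window, a small set
of fragment m/z channels on a single-quadrupole instrument. Each channel
yields a time/intensity trace (an extracted ion chromatogram, EIC). A
*target* is a compound with a known reference stick spectrum and a known
retention time (RT, seconds) and/or retention index (RI, unitless). The
pipeline answers, per target and run: *was the compound there, and at what
intensity?* — and, at method-design time: *which fragments should be
monitored in the first place?*

## Fragment selection

Two analytes **overlap** when their RIs differ by at most `ri_tolerance`
(default 20 RI units), falling back to RTs within `rt_tolerance` (default
10 s) when either side lacks an RI. For each candidate fragment the
penalty is

    P = (1/a) · Σ_k exp(−|r_i − r_k| / δR)

over all fragments of overlapping analytes sharing the same nominal mass.
`δR` defaults to 10 RI units: an interferer 10 RI units away counts e⁻¹
as much as a perfect co-elution, which on a standard 30 m column
corresponds to a few seconds of separation — about one peak width.
Fragments below `min_rel_intensity` (default 0.05) of the mean of the
top-3 intensities are removed before ranking: a unique but barely
detectable fragment makes a poor quantifier. Ties in penalty (typically
at 0) break by descending intensity, then ascending mass, so the most
abundant clean fragment becomes the quantifier. `n_default` is 4 — one
quantifier plus three qualifiers, the usual shape of published SIM
panels. The penalty function is a pluggable strategy (`penalty_fn`
argument) for users who want a different uniqueness measure.

The sharing set is restricted to overlapping analytes by default
(`restrict_to_overlapping=True`); comparing against the whole library
regardless of retention is available behind the flag but over-penalizes
fragments shared with compounds that can never co-elute.

RT window planning is a greedy left-to-right grouping: a window closes
when adding the next target would exceed the per-window channel budget or
leave a gap larger than `min_gap`. The budget is exposed as a parameter
because the instrument-side limit depends on dwell times and duty cycle,
which the software cannot know. Window bounds are midpoints between
adjacent windows' edge targets, padded by the search half-window at the
extremes.

## Preprocessing

All preprocessing is per channel — each monitored mass carries its own
chemical background.

**Baseline.** Two passes over blocks of `baseline_window` (default 60 s,
≫ peak width): a rolling low-quantile envelope flags samples more than 3
noise sigmas above it as peak territory; the baseline then interpolates
the per-block *median of the unflagged samples*. The median of
peak-free samples is unbiased under symmetric noise, whereas a raw
rolling minimum sits ≈2.5 noise sigmas low and would systematically
inflate every apex and area by that amount — several percent at
signal-to-noise 20. The noise scale is estimated robustly from first
differences (`1.4826·median|Δy|/√2`), which slow chromatographic
structure barely touches.

**Smoothing and detection.** A Savitzky–Golay filter (window 7 scans,
order 2) produces a *detection track*: local maxima above
`noise_k`(=3)× the noise floor, plateaus reporting their center scan.
The smoothed copy steers apex finding and support walks only — heights
and areas are always measured on the unsmoothed baseline-corrected
signal, because polynomial smoothing attenuates a σ = 4-scan Gaussian
apex by ~0.5%, a bias with no compensating benefit once a model fit does
the averaging.

**Shape quality (QS).** Each candidate peak is fit with a Gaussian
`h·exp(−(t−μ)²/2σ²)` over its local support, symmetrized around the
apex. QS is the coefficient of determination of the model against the
detection track, clipped to [0, 1]; fit failure gives 0. Two constraints
matter: μ is bounded to within two scans of the apex, and the window is
symmetric — together they prevent a monotone ramp from being fit by a
distant Gaussian flank (unconstrained, a ramp reaches R² ≈ 0.98; with
the constraints it scores ≈ 0.1). Qualifiers with QS below `qs_min`
(default 0.5) are excluded from the spectral match and reported in
`excluded_masses`; the quantifier anchor is always retained.

**Quantification.** The apex intensity is the fitted Gaussian height
(fallback: the trace value at the apex scan). At signal-to-noise 20 the
fitted height is unbiased with a sampling sd of ≈2.3% of the true
height — the Cramér–Rao bound for this model, against ≈3% for a single
smoothed sample. The AUC is the trapezoidal area over the walk-based
peak support; its noise floor at SNR 20 is ≈2.4% sd, which is a property
of integrating white noise over the peak's width, not of the estimator.
These two numbers calibrate expectations: a "within 5%" recovery claim
at SNR 20 is a ≈2σ statement per peak.

**Grouping.** Quantifier apexes within `expected RT ± search_halfwidth`
(default ±4 s — read as a half-width; configurable when RT drift is
larger) anchor candidate groups; each qualifier contributes its nearest
apex within `coelution_tol` (2 scans) of the anchor. No deconvolution of
overlapping mixtures is attempted beyond apex assignment and per-peak
support — consistent with anchoring everything on the quantifier
channel.

## RI calibration

Standards (e.g. a FAME or alkane ladder) define knots of a piecewise
linear RT→RI map, exact at every standard — the standard Kovats-style
construction. Outside the ladder the terminal segment slopes extrapolate.
Replicate injections can be averaged first (`method="mean"`). The map is
strictly monotone, so its inverse predicts the expected RT of an RI-only
target. With no standards the pipeline matches on RT alone and the RI
similarity term is neutral (1.0).

## Identification scores

See the README for the formulas. Numerical decisions:

- The dot-product is the cosine of elementwise-weighted vectors
  `u = m^w_m · a^w_a` on the union grid (defaults `w_m = 1`,
  `w_a = 0.5`: mass-weighted, intensity-compressed — de-emphasizing the
  base peak's dominance). This form is symmetric, bounded, and exactly 1
  for proportional spectra.
- The ratio score's α is a *ratio of ratios*
  `(a₁k/a₁ℓ)/(a₂k/a₂ℓ)`, so identical spectra score exactly 1; a variant
  multiplying the two like-oriented ratios is kept behind
  `alpha_variant="as_printed"` for comparison, and a sequential
  (adjacent-fragments-by-mass) variant behind
  `ratio_score_variant="sequential"`. All C(N,2) unordered pairs
  contribute by default.
- Shared fragments require both intensities > 0; zero-intensity grid
  entries never enter a ratio (division safety).
- Apex and AUC spectra are normalized to base peak 1000 before matching.
- The overall score is `(w·S_apex + (1−w)·S_AUC) · exp(−|ΔRI|/δR)` with
  `w = 0.5`, `δR = 10`, detection cutoff 0.8. Ties within 1e-12 break
  toward the group closest to the expected RT.

## Synthetic data

`simgc.simulate` generates the study conditions every test runs under.
It emulates a spike-in method-development experiment: Gaussian
chromatographic peaks (σ = 2 s) on a drifting baseline (level 50 counts,
0.02 counts/s) sampled at 0.5 s, white detector noise, and optional
interfering peaks on shared masses. The reference study is 10 targets ×
3 technical-replicate runs; quantifier heights span 500–5000 counts and
the noise sigma is set to (weakest quantifier height)/20, i.e. every
target at signal-to-noise ≥ 20. Randomness is fully reproducible: one
master seed, with per-run/per-channel child generators so adding a run
never reshuffles another.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate: tailing/fronting peak shapes (an exponentially modified
Gaussian stress-mode is deliberately out of the default), retention
drift between runs, correlated (1/f) detector noise, isotope patterns,
and realistic EI fragmentation. Results on real data depend on those
factors; the synthetic studies validate the estimators and the pipeline
logic, not instrument physics.

The dilution-series check runs six two-fold levels at high SNR rather
than the full 2⁻¹² range of a real spike-in series: below a certain
level peaks sink beneath the noise by construction, and the test's point
is monotone AUC recovery, not limit-of-detection estimation.

## Problem sizes

Test and acceptance workloads are sized for a laptop-class single core:
the reference study (10×3, ~40 channels × ~900 scans), 50-replicate
metrology experiments, 200–500-pair oracle comparisons, 20–30-entry
random libraries. The full suite runs in a few seconds.

## Known limitations

- Peak model is a pure Gaussian; strongly tailed peaks will score lower
  QS and their fitted heights will be biased. The peak-detection stage is
  replaceable (any function returning apex indices).
- No multi-component curve resolution: two analytes co-eluting *on the
  same channel* within the coelution tolerance are not separated.
- MSL dialect support covers NIST/AMDIS-style exports (parenthesized or
  bare pairs); MSP and vendor variants are out of scope.
- The netCDF layer targets ANDI-MS classic NetCDF-3 files; NetCDF-4/HDF5
  containers are not read.
- Channel binning assumes nominal-mass SIM (tolerance 0.3 Da); high-
  resolution data needs a different binning strategy.
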