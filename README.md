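# simgc — targeted GC-SIM-MS analysis

`simgc` is a toolkit for **targeted analysis of GC-MS data acquired in
selected ion monitoring (SIM) mode** on single-quadrupole instruments —
the workhorse setup of targeted metabolomics panels (amino acids, organic
acids, labeled internal standards spiked into plasma, ...). In SIM mode the
instrument dwells on a handful of fragment m/z channels per retention-time
window instead of scanning the full mass range, trading coverage for
sensitivity. That design shifts the analytical burden to two places this
package addresses:

1. **Method design** — picking, for every target, the *quantifier* fragment
   (used for quantification) and a few *qualifier* fragments (used to
   confirm identity via their intensity ratios), such that no co-eluting
   background compound shares them; and grouping targets into RT
   acquisition windows.
2. **Data analysis** — turning the acquired per-channel traces back into
   per-target intensities: baseline correction, peak detection, retention
   index (RI) calibration, identification by spectral/RI similarity, and
   apex/area quantification.

## The scores at the core

**Fragment selection.** Fragment *j* of target *i* (intensity
*a<sub>ij</sub>*, nominal mass *m<sub>ij</sub>*) is ranked by the penalty

```
P_ij = (1 / a_ij) · Σ_k exp( −|r_i − r_k| / δR )
```

summing over all fragments of *overlapping* analytes (RI within a
tolerance) that share the same nominal mass; *r* is the retention index and
*δR* controls how fast a retention mismatch forgives a shared mass. Lower
is better: an unshared fragment scores 0, and among shared ones, higher
intensity and larger retention separation win. Fragments weaker than a
fraction (default 5%) of the mean of the target's top-3 intensities are
discarded up front.

**Identification.** Because a SIM spectrum has only a few sticks, a plain
weighted dot-product is too permissive. Matching combines it with an
intensity-*ratio* score on the union mass grid of unknown (1) and
reference (2):

```
S_12   = (N₁·S_DP + N₁∩₂·S_PR) / (N₁ + N₁∩₂)
S_DP   = cosine of u_i = m^w_m · a_i^w_a          (weighted dot-product)
S_PR   = mean over fragment pairs (k,ℓ) of min(α, 1/α),
         α = (a₁k/a₁ℓ) / (a₂k/a₂ℓ)                (all C(N,2) pairs)
```

Apex-based and area-based versions of S₁₂ are blended with weight *w*
(default 0.5) into the chromatographic score, which is multiplied by the
RI similarity `S_R = exp(−|r₁−r₂|/δR)` for the overall score. A target
counts as detected when the overall score reaches the cutoff (default
0.8). Each fragment peak also gets a Gaussian shape-quality score
QS ∈ [0, 1]; badly shaped qualifier EICs are excluded from the match
rather than allowed to drag it down.

## Worked example

Simulate a small spike-in style study with known ground truth, then
process it end to end:

```
$ simgc simulate --seed 3 --n-targets 3 --n-runs 2 --out-dir demo
wrote 2 runs, library and truth to demo

$ simgc process --run demo/run_00.cdf --run demo/run_01.cdf \
    --background demo/library.msl --target-table demo/targets.csv \
    --out-dir demo/out
processed 3 targets x 2 runs; 6/6 cells detected; results in demo/out
```

The results matrix (`demo/out/results.csv`) has one row per target and a
column group per run — quantifier apex intensity, quantifier area (AUC),
overall similarity score, attained RT (seconds), and the detection flag:

```
target,run_00:apex,run_00:auc,run_00:score,run_00:rt,run_00:detected,...
target_00,3397.56,17414.2,0.991408,297.842,True,...
target_01,4523.54,22577.7,0.968975,338.342,True,...
target_02,2162.66,11128.9,0.900076,381.842,True,...
```

Compare with the generated truth (`demo/truth.csv`): target_00's
quantifier (m/z 103) was simulated at height 3418.5 eluting at 297.84 s —
the pipeline reports an apex of 3397.6 (−0.6%) at 297.84 s with an overall
score of 0.99. Scores below the 0.8 cutoff would leave the intensity
cells empty (never zero-filled).

Other subcommands: `simgc optfrag` (fragment selection → SIM method plan
with RT windows), `simgc calibrate` (piecewise-linear RT→RI model from RI
standards), `simgc plot-tic` / `simgc plot-eic` (chromatogram figures).
Everything is equally usable as a library — see `simgc.run_study`,
`simgc.select_fragments`, `simgc.simulate.make_study`.

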