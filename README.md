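# imsync

Interpersonal movement synchrony (IMS) from pose-landmark kinematics.

Two people sit face to face and simply look at each other. Do their
spontaneous, uninstructed body movements become temporally coupled — and if
so, how fast, and through which body parts? `imsync` implements the full
analysis chain for this question, from raw 2-D pose-keypoint trajectories
(25 body + 2x21 hand landmarks per person, with per-frame detection
confidences) to statistical inference, for a 2x2 within-dyad design crossing
interpersonal proximity (Far/Near) with visual contact (Vision/NoVision):

1. **Preprocessing** — outlier removal (3 within-trial SDs), interpolation of
   missing detections, 1-s moving-mean smoothing, direction-agnostic movement
   velocity (pixels/frame), z-scoring, and grouping of the 67 landmarks into
   10 body parts.
2. **Synchrony matrices** — per-trial 10x10 Pearson correlation matrices
   between the partners' part-velocity series, averaged within condition and
   symmetrised to 55 unique body-part combinations ("r" below).
3. **Permutation inference** — a consistency test of IMS against zero (t
   across dyads vs. a null built by shuffling one partner's time series,
   1000 permutations by default) and a permutation 2x2 repeated-measures
   ANOVA (proximity x vision) per combination, both BH-FDR corrected, with
   Cohen's d and generalized eta squared effect sizes.
4. **Intra-personal velocity-range ANOVA** — a 2x2x10 within-dyad ANOVA
   (proximity x vision x body part) with unconditional Greenhouse–Geisser
   correction and Holm–Bonferroni post-hocs.
5. **Lag analysis** — resampling to a 0.1-s grid, ±10-s cross-correlation
   functions, absolute peak lags per combination, Vision vs NoVision compared
   by Wilcoxon signed-rank.
6. **Circular statistics** — analytic-signal instantaneous phase, Fisher–Lee
   circular correlation, and the circular variance of the continuous relative
   phase.
7. **A synthetic dyad generator** — sparse fast-rising movement bursts over a
   noisy baseline, with partner coupling (probability, lag, body-part
   response matrix) present only in configurable condition cells, plus
   injected missing samples and outlier spikes — so the entire chain is
   verifiable against known ground truth without any recorded data.

The package is organised as an analysis project: every computation lives in
`src/imsync/` (importable, tested), and the numbered scripts under
`analysis/` are thin narrative drivers that run the stages and write tidy
tables under `results/`.

## Worked example

Generate the default synthetic study (23 dyads x 12 x 120-s trials, coupling
only under Vision) and run the synchrony and permutation analyses:

```sh
python analysis/03_synchrony_permutation.py --n-perm 500
```

prints

```
mean coefficient by condition (n=23 dyads, n_perm=500):
   Far-NoVision  mean r = -0.0008   combos with q<0.05: 0/55
   Far-Vision    mean r = +0.0553   combos with q<0.05: 55/55
  Near-NoVision  mean r = +0.0006   combos with q<0.05: 0/55
  Near-Vision    mean r = +0.0583   combos with q<0.05: 55/55
permutation ANOVA: vision effect q<0.05 for 55/55 combos; proximity: 0/55; interaction: 0/55
```

Read: dyad-averaged synchrony coefficients center on zero when the partners
cannot see each other and are positive in both Vision conditions; the
consistency test finds every body-part combination significant only under
Vision, and the permutation ANOVA attributes this to the vision main effect
with no proximity effect — synchrony depends on seeing the partner, not on
sitting closer.

The lag driver on a reduced study (12 dyads, 60-s trials):

```sh
python analysis/05_crosscorr_lags.py
```

```
   vision: mean |peak lag| = 0.13s, Q1 = 0.10s, Q3 = 0.20s, 100.0% of peaks < 0.5s
 novision: mean |peak lag| = 5.37s, Q1 = 3.05s, Q3 = 7.35s, 1.8% of peaks < 0.5s
Wilcoxon (NoVision vs Vision peak lags, 55 combos): Z = 6.45, p = 1.10e-10
```

Vision-condition cross-correlations peak within a few hundred milliseconds
of lag zero (the generator plants 0.2-s coupling), while NoVision peaks
scatter over the ±10-s window.

The other drivers: `01_simulate.py` writes a small landmark-level demo
dataset (keypoint JSON + long CSV + manifest + ground truth),
`02_preprocess.py` cleans it into velocity panels with a QC report,
`04_velocity_range_anova.py` runs the intra-personal 2x2x10 ANOVA,
`06_circular_phase.py` the circular-phase statistics, and `07_validation.py`
reduced-size ground-truth validation experiments.

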