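# Methods

This note documents the models, estimators and numerical choices behind
`imsync`, and what the synthetic validation experiments do and do not show.

## The scientific setting

Two seated people who can (or cannot) see each other produce spontaneous,
uninstructed body movements. The question is whether those movements become
temporally coupled across the pair — interpersonal movement synchrony (IMS) —
and, if so, how fast the coupling operates and which body parts carry it.
The measurable is a set of 2-D pose-landmark trajectories per participant and
trial (25 body landmarks plus 21 per hand, pixel coordinates with a detection
confidence per frame), recorded under a 2x2 within-dyad design: interpersonal
proximity (Far/Near) x visual contact (Vision/NoVision), three 120-s trials
per cell.

## Preprocessing: landmarks to body-part velocity

Per participant and trial, the chain is:

1. **Outlier removal.** Samples more than `outlier_sd` (default 3) SDs from
   the within-trial mean, on either axis, per landmark, are marked missing.
   The statistics use only non-missing samples; a constant trajectory (SD=0)
   loses nothing.
2. **Interpolation.** Missing samples (zero-confidence detections and removed
   outliers) are filled by linear interpolation over the frame index.
   Leading/trailing gaps take the nearest valid value — extrapolation at the
   trial edges would manufacture spurious velocity.
3. **Coordinate smoothing.** Centered moving mean, 1-s window, shrinking at
   the edges. Windows in seconds convert to the nearest odd frame count >= 1
   (ties round up), so the window is symmetric around each sample.
4. **Velocity.** Default `radial_derivative`: the absolute first difference
   of the radial distance `r_t = sqrt(x_t^2 + y_t^2)` — the rate of change of
   body-part location regardless of direction, in pixels/frame. The more
   conventional `frame_displacement` mode (`sqrt(dx^2 + dy^2)`) is exposed
   because the two genuinely differ (e.g. circular motion about the image
   origin has zero radial derivative but nonzero displacement); all shipped
   analyses use the default.
5. **Velocity smoothing.** A second 1-s moving mean.
6. **Normalisation.** Each landmark's velocity is z-scored within the trial,
   member landmarks are averaged into ten parts (Head, Torso, arms, hands,
   knees, feet), and each part column is re-standardised. Z-scoring before
   grouping keeps every landmark on equal footing inside its group;
   re-standardising makes the output contract exact (mean 0, SD 1 to 1e-9).
   A per-session scope is available.
7. **QC.** Trials whose maximum per-part raw-velocity variance exceeds
   `k` x the median of that statistic across trials (default k = 10) are
   flagged and excluded downstream — a reproducible stand-in for visual
   artifact screening.

The landmark -> part grouping is explicit configuration with a shipped
default. The trunk split is genuinely underdetermined (only group counts are
recoverable); the default puts Neck with the head (`Head` = Nose, LEye, REye,
Neck; `Torso` = MidHip, LHip, RHip), assigns ankles to the feet, and drops
the ears with a logged notice. `default_grouping(neck_group="Torso")` gives
the alternative trunk split. Knees are single landmarks; hands use all 21
landmarks each.

The intra-personal movement measure is the **velocity range** (max − min over
time) of the *pre-normalisation* velocity, computed per landmark, averaged
within part, across the trials of a condition, and across the two
participants of a dyad, giving one value per dyad x condition x part in
pixels/frame.

## Synchrony and permutation inference

**Matrices.** Per trial, Pearson correlations between all 10 x 10 part pairs
of the two participants; per condition, the element-wise mean over its
(unflagged) trials; then symmetrisation `(M + M^T)/2`, since the participants
have no roles — leaving 55 unique combinations (10 homologous, 45
heterologous). All inference operates on the symmetrised coefficients.

**Consistency test** (is IMS nonzero?). Per condition and combination: the
genuine statistic is the one-sample t (across dyads) of the coefficients
against zero. The null is built by shuffling the full velocity time series of
one participant per trial (destroying temporal alignment, preserving
marginals), recomputing the coefficient path exactly (trial matrices ->
condition average -> symmetrise), and taking the t across dyads; repeated
`n_perm` times. p is the fraction of pseudo t exceeding the genuine t
(one-sided, strict, no smoothing by default; a guaranteed-positive
`(count+1)/(n_perm+1)` variant is exposed and used by the replicate-level
validation experiments — see *Numerical choices*). The shuffled partner is
drawn uniformly per replicate; with symmetrised coefficients the choice is
immaterial, which the single-combination fast path exploits by always
shuffling partner B. BH-FDR is applied across the 55 combinations within a
condition. Effect size: one-sample Cohen's d (mean/SD of the dyad-level
coefficients).

**Permutation 2x2 ANOVA** (does IMS depend on the conditions?). Per
combination, the genuine F values of the within-dyad proximity x vision ANOVA
on condition-level coefficients are compared against pseudo-F distributions
from the same shuffling scheme; FDR across combinations separately per
effect. The 2x2 within-subject F values come from the closed-form
repeated-measures decomposition (each 1-df effect is the paired t^2 of its
contrast scores); generalized eta squared uses all error SS plus the
between-dyad SS in the denominator. The consistency test and the ANOVA may
share one set of pseudo condition-level coefficients — each test's null needs
only exchangeability under its own hypothesis, not independence from the
other test — which halves the permutation cost.

## Intra-personal velocity-range ANOVA

A fully within-dyad 2 x 2 x 10 ANOVA (proximity x vision x body part) on the
range table, via the standard sums-of-squares decomposition (inclusion–
exclusion over marginal means; each effect's error term is its
dyad-interaction SS). Greenhouse–Geisser epsilon is computed per effect from
the covariance of orthonormal contrast scores,
`eps = (tr S)^2 / (d tr S^2)`, clipped to `[1/d, 1]`, and applied
*unconditionally* to every effect with more than one numerator df —
condition-on-a-sphericity-test behaviour is not reproducible, so corrected
and uncorrected df are always reported side by side. Post-hoc body-part
comparisons are two-sided paired t tests on the part marginals with
Holm–Bonferroni adjustment.

## Cross-correlation lag analysis

Series are resampled by linear interpolation onto a regular 0.1-s grid
(0–120 s inclusive; a trial sampled at 30 Hz ends at 119.97 s, so the last
grid point is dropped). The cross-correlation function evaluates, at every
lag in ±10 s, the Pearson correlation over the overlapping segment (bounded
in [−1, 1] by construction; lags with under 10 overlapping samples are
dropped). Functions are averaged across trials within the Vision (or
NoVision) cells, then across dyads, and each combination's peak is the
absolute lag of the maximum coefficient, exact ties breaking toward zero lag
(conservative with respect to rapid-synchrony claims). The Vision vs NoVision
peak-lag distributions (paired by combination) are compared with a Wilcoxon
signed-rank test: zero differences dropped, tie-corrected normal
approximation with a signed Z from the positive-rank sum for >= 6 nonzero
pairs, the exact distribution otherwise.

## Circular statistics

Instantaneous phase is the angle of the analytic signal (Hilbert construction)
of the mean-centered velocity; an optional Butterworth low-pass (default
cutoff 2 Hz, off by default) can band-limit the series first, because the
phase of broadband bursty signals is intrinsically noisy. Partner phases are
compared by the Fisher–Lee circular correlation (sine-deviation form about
circular means), and the continuous relative phase `wrap(phi_a − phi_b)` is
summarised by its circular variance `V = 1 − Rbar`; V near 0 means phase
locking.

## The synthetic dyad generator

The generator defines the study conditions used throughout the validation:
23 dyads x 3 trials per condition cell x 120 s at 30 Hz. Each body part of
each participant emits spontaneous movement *bursts* — a homogeneous Poisson
process (default 3 events/min per part) of fast-rising, slower-decaying
velocity events, kernel `(1 − e^{−t/rise}) e^{−t/decay}` with rise 0.1 s and
decay 0.5 s, lognormal amplitudes (sigma 0.4) — over a small smooth positive
baseline (softplus of AR(1) noise). Part amplitude scales are heterogeneous
(hands largest, torso smallest; defaults 2.6 for RightHand down to 0.4 for
Torso, in pixels/frame), giving the hands-move-most intra-personal profile.

Under coupled conditions (default: both Vision cells), each spontaneous burst
triggers, with probability `coupling_prob` (default 0.8), a response burst in
the partner after `coupling_lag` (default 0.2 s) plus Gaussian jitter (SD
0.05 s), in a part drawn from a row-stochastic response matrix — uniform by
default (synchrony spreads over all combinations), with a homologous
(mimicry-style) preset. Spontaneous rates are *thinned* under coupling so the
expected total event rate matches the uncoupled rate: coupling changes when
people move, not how much, so visual contact leaves intra-personal velocity
ranges untouched — exactly the pattern the range ANOVA is expected to find.
Near trials scale amplitudes by `proximity_amplitude_gain` (default 1.5),
planting the proximity effect. Coupling is bidirectional by default; a
leader–follower mode exists because a *directional* lag is the only setting
in which "the injected lag" is identified (see below).

Landmark-level output embeds the same bursts as coherent displacements of all
member landmarks along a random image direction, on a plausible seated
skeleton, with AR(1) positional jitter, and injects zero-confidence missing
samples (default 8% of samples) and coordinate spikes (default 0.68%),
mirroring typical pose-estimation dropout. The velocity-level fast path emits
part-velocity panels directly from the same event process and is what the
study-scale statistical experiments use.

What the generator does *not* emulate: biomechanical skeleton constraints,
realistic pose-estimator error structure (its dropout is i.i.d., real dropout
is occlusion-clustered), drifts in camera geometry, or oscillatory
(rhythmic) coordination — bursts are transient events, not sustained
oscillations. Passing tests therefore certify the statistical chain under a
plausible burst-coupling model, not the upstream pose-estimation quality on
real video.

## Validation experiments and problem sizes

* **Type-I calibration**: 400 uncoupled single-combination tests, 23 dyads,
  120-s series, 200 permutations; the rejection rate at alpha = 0.05 must sit
  in the binomial 95% band [0.031, 0.074].
* **Planted-coupling detection**: 20 replicate studies (23 dyads, full
  layout) with homologous Vision-only coupling, p_c = 0.8, lag 0.2 s, 200
  permutations; a replicate succeeds when all coupled combinations reach
  q < 0.05 in both Vision cells and no combination is significant in either
  NoVision cell; the permutation ANOVA must flag the vision main effect.
  These replicate-level experiments use the smoothed p estimator: at
  n_perm = 200 the strict fraction hits exactly zero with probability
  ~1/200 per null combination, and a zero p survives any FDR threshold, so
  the strict estimator cannot deliver valid family-wise behaviour at this
  permutation count (the literal strict fraction remains the package
  default, sized for n_perm = 1000).
* **Lag recovery**: injected leader–follower lags 0.1–1.0 s, two replicate
  datasets each (23 dyads x 6 Vision trials), homologous coupling; the
  dyad-averaged cross-correlation peak must land within one 0.1-s grid step
  for >= 95% of (lag, replicate, combination) measurements. Directional
  coupling is an identifiability condition, not a convenience: with
  symmetric coupling the averaged function superposes bumps at +tau and
  −tau whose joint maximum is pulled toward zero once tau is below the
  burst-autocorrelation width (~0.5 s).
* **Range-ANOVA pattern**: one default study; proximity and body-part main
  effects significant, vision not.

The analysis drivers use reduced sizes where runtime matters (the lag and
circular drivers run 12 dyads x 60-s trials); all scaled-down sizes are
stated in the scripts themselves.

## Numerical choices, degenerate inputs, limitations

* All randomness flows from one seeded `numpy` Generator per entry point;
  reruns are bit-identical. Permutation nulls are accumulated in single
  precision (they feed rank comparisons only); genuine statistics are double.
* Zero-variance inputs are *signalled* (Pearson, Cohen's d, circular
  correlation, phase of a constant series raise), never silently mapped to 0.
  Degenerate ANOVA tables: zero effect with zero error gives F = 0, positive
  effect with zero error gives F = +inf; round-off residue in the SS
  decomposition is flushed relative to the table's uncentered magnitude so
  constant tables are exact.
* Partner panels may differ by at most 2 frames (truncated with a warning);
  larger mismatches error out.
* The Fisher–Lee circular correlation is undefined when either phase series
  has zero sine dispersion about its circular mean; this is raised, and can
  genuinely occur for near-silent body parts.
* The consistency test's full-series permutation destroys autocorrelation as
  well as coupling; the calibration experiment shows the dyad-level t
  comparison is nonetheless near-nominal at the study's series length. A
  circular-shift surrogate that preserves autocorrelation is exposed for
  sensitivity analyses.
* Velocities are camera-frame pixels/frame; no calibration to metric units is
  attempted, so amplitude comparisons across cameras or seating distances
  are not meaningful — only within-design contrasts are.
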