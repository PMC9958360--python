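"""Landmark trajectories -> cleaned, z-scored body-part velocity panels.

The cleaning chain runs, per trial and participant:

1. outlier removal (samples beyond ``outlier_sd`` trial SDs on either axis),
2. 1-D linear interpolation of missing samples (nearest-value extension at
   the trial edges),
3. a centered moving mean over the coordinates (1 s window),
4. velocity extraction (default the radial derivative
   ``v_t = |r_{t+1} - r_t|`` with ``r_t = sqrt(x_t^2 + y_t^2)``; the
   conventional frame displacement ``sqrt(dx^2 + dy^2)`` is available as an
   alternative mode),
5. a second moving mean over the velocity (1 s window),
6. z-scoring of each landmark's velocity within the trial,
7. averaging of member landmarks into the ten body-part streams, followed by
   re-standardisation of each part column.

Velocities are pixels/frame before normalisation and unitless after.  The
panel keeps the pre-normalisation part velocities alongside, because the
intra-personal velocity-range analysis operates on those.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .landmarks import BodyPartGrouping, LandmarkSeries, PART_NAMES, default_grouping

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    outlier_sd: float = 3.0
    smooth_window: float = 1.0          # seconds, both smoothing passes
    velocity_mode: str = "radial_derivative"
    zscore_scope: str = "per_trial"
    artifact_variance_factor: float = 10.0  # flag trials > factor x median variance

    def __post_init__(self) -> None:
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")
        if self.smooth_window <= 0:
            raise ValueError("smooth_window must be positive")
        if self.velocity_mode not in ("radial_derivative", "frame_displacement"):
            raise ValueError("velocity_mode must be 'radial_derivative' or 'frame_displacement'")
        if self.zscore_scope not in ("per_trial", "per_session"):
            raise ValueError("zscore_scope must be 'per_trial' or 'per_session'")


@dataclass
class VelocityPanel:
    """Z-scored body-part velocity time series for one participant/trial."""

    participant_id: str
    trial_id: str
    frame_rate: float
    part_names: tuple[str, ...]
    velocity: np.ndarray            # (frames-1, 10), z-scored
    raw_velocity: np.ndarray        # (frames-1, 10), pixels/frame, nonnegative
    part_range: np.ndarray          # (10,), per-landmark range averaged within part
    qc_flag: bool = False
    provenance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.velocity.shape[0]


def window_frames(window_seconds: float, frame_rate: float) -> int:
    """Convert a window in seconds to the nearest odd frame count >= 1
    (ties round up)."""
    w = window_seconds * frame_rate
    return max(1, 2 * math.floor(w / 2) + 1)


def remove_outliers(series: LandmarkSeries, outlier_sd: float = 3.0
                    ) -> tuple[LandmarkSeries, float]:
    """Mark samples lying more than ``outlier_sd`` SDs from the within-trial
    mean (on either axis) as missing.  Returns the cleaned series and the
    fraction of previously-valid samples removed.

    Statistics are computed per landmark and axis over non-missing samples;
    a zero-SD (constant) trajectory yields no removals.
    """
    out = series.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(out.coords, axis=0, keepdims=True)
        sd = np.nanstd(out.coords, axis=0, keepdims=True)
    dev = np.abs(out.coords - mean)
    with np.errstate(invalid="ignore"):
        outlier = (dev > outlier_sd * sd).any(axis=2)  # either axis
    valid_before = ~series.missing_mask
    n_removed = int(np.count_nonzero(outlier & valid_before))
    out.coords[outlier] = np.nan
    out.confidence[outlier] = 0.0
    total_valid = int(np.count_nonzero(valid_before))
    frac = n_removed / total_valid if total_valid else 0.0
    all_missing = (out.confidence == 0).all(axis=0)
    if all_missing.any():
        bad = [out.landmark_names[i] for i in np.flatnonzero(all_missing)]
        logger.warning("landmarks with no valid samples after outlier removal: %s", bad)
    return out, frac


def interpolate_missing(series: LandmarkSeries) -> LandmarkSeries:
    """Fill missing samples by linear interpolation over the frame index,
    extending the nearest valid value across leading/trailing gaps.

    Landmarks with fewer than 2 valid samples cannot be interpolated; they are
    left entirely missing (and dropped later, with a warning here).
    """
    out = series.copy()
    t = np.arange(out.n_frames, dtype=float)
    dropped = []
    for j in range(out.n_landmarks):
        valid = out.confidence[:, j] > 0
        n_valid = int(valid.sum())
        if n_valid == out.n_frames:
            continue
        if n_valid < 2:
            dropped.append(out.landmark_names[j])
            out.coords[:, j, :] = np.nan
            out.confidence[:, j] = 0.0
            continue
        for ax in range(2):
            y = out.coords[:, j, ax]
            out.coords[:, j, ax] = np.interp(t, t[valid], y[valid])
        out.confidence[~valid, j] = np.nextafter(0.0, 1.0)  # filled, minimally trusted
    if dropped:
        logger.warning("landmarks dropped (<2 valid samples): %s", dropped)
    return out


def moving_mean(x: np.ndarray, window_seconds: float, frame_rate: float,
                axis: int = 0) -> np.ndarray:
    """Centered moving mean with shrinking windows at the edges.

    The window is converted to the nearest odd frame count; edge samples
    average over however much of the window falls inside the series.  A
    window at least as long as the series collapses to the global mean
    (with a warning).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    w = window_frames(window_seconds, frame_rate)
    if w >= n:
        if w > n:
            warnings.warn("moving-mean window exceeds series length; using global mean")
        return np.broadcast_to(x.mean(axis=axis, keepdims=True), x.shape).copy()
    x = np.moveaxis(x, axis, 0)
    h = w // 2
    csum = np.cumsum(x, axis=0)
    zero = np.zeros((1,) + x.shape[1:])
    csum = np.concatenate([zero, csum], axis=0)  # csum[i] = sum of x[:i]
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    sums = csum[hi] - csum[lo]
    counts = (hi - lo).reshape((-1,) + (1,) * (x.ndim - 1))
    return np.moveaxis(sums / counts, 0, axis)


def compute_velocity(coords: np.ndarray, mode: str = "radial_derivative") -> np.ndarray:
    """Per-landmark nonnegative movement velocity, pixels/frame.

    ``radial_derivative``: absolute first difference of the radial distance
    ``r_t = sqrt(x_t^2 + y_t^2)`` — displacement along the radial direction
    from the image origin.  ``frame_displacement``: Euclidean inter-frame
    displacement.  Input ``(frames, landmarks, 2)``, output
    ``(frames - 1, landmarks)``.
    """
    coords = np.asarray(coords, dtype=float)
    if mode == "radial_derivative":
        r = np.hypot(coords[:, :, 0], coords[:, :, 1])
        return np.abs(np.diff(r, axis=0))
    if mode == "frame_displacement":
        d = np.diff(coords, axis=0)
        return np.hypot(d[:, :, 0], d[:, :, 1])
    raise ValueError(f"unknown velocity mode {mode!r}")


def zscore(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Exact z-score along ``axis``; zero-variance columns come out as NaN."""
    x = np.asarray(x, dtype=float)
    mean = np.nanmean(x, axis=axis, keepdims=True)
    sd = np.nanstd(x, axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd  # constant columns come out as 0/0 = NaN
    return z


def group_and_normalize(landmark_velocity: np.ndarray,
                        landmark_names: tuple[str, ...],
                        grouping: BodyPartGrouping) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each landmark's velocity, average members into parts, then
    re-standardise each part column.

    Returns ``(z_panel, raw_panel)`` of shape ``(samples, 10)``: the z-scored
    part streams and the pre-normalisation part velocities (plain member
    means, pixels/frame).  Landmarks that are entirely NaN (dropped upstream)
    are excluded from their group mean; a part whose members are all dropped
    yields a NaN column.
    """
    v = np.asarray(landmark_velocity, dtype=float)
    idx = grouping.indices(landmark_names)
    vz = zscore(v, axis=0)
    z_cols, raw_cols = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for part in PART_NAMES:
            members = idx[part]
            raw_cols.append(np.nanmean(v[:, members], axis=1))
            z_cols.append(np.nanmean(vz[:, members], axis=1))
    raw_panel = np.stack(raw_cols, axis=1)
    z_panel = zscore(np.stack(z_cols, axis=1), axis=0)
    return z_panel, raw_panel


def preprocess_trial(series: LandmarkSeries,
                     grouping: BodyPartGrouping | None = None,
                     config: PreprocessConfig | None = None) -> VelocityPanel:
    """Run the full cleaning chain on one participant/trial."""
    grouping = grouping or default_grouping()
    config = config or PreprocessConfig()

    missing_frac = float(series.missing_mask.mean())
    cleaned, outlier_frac = remove_outliers(series, config.outlier_sd)
    filled = interpolate_missing(cleaned)
    smooth = moving_mean(filled.coords, config.smooth_window, series.frame_rate, axis=0)
    v = compute_velocity(smooth, config.velocity_mode)
    v = moving_mean(v, config.smooth_window, series.frame_rate, axis=0)

    # keep only landmarks the grouping uses, in their original columns
    z_panel, raw_panel = group_and_normalize(v, filled.landmark_names, grouping)

    # per-landmark range (max - min over time), averaged within part
    idx = grouping.indices(filled.landmark_names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        lm_range = np.nanmax(v, axis=0) - np.nanmin(v, axis=0)
        part_range = np.array([np.nanmean(lm_range[idx[p]]) for p in PART_NAMES])

    empty_parts = [p for i, p in enumerate(PART_NAMES)
                   if np.isnan(z_panel[:, i]).all()]
    return VelocityPanel(
        participant_id=series.participant_id,
        trial_id=series.trial_id,
        frame_rate=series.frame_rate,
        part_names=PART_NAMES,
        velocity=z_panel,
        raw_velocity=raw_panel,
        part_range=part_range,
        qc_flag=bool(empty_parts),
        provenance={
            "missing_frac": missing_frac,
            "outlier_frac": outlier_frac,
            "empty_parts": empty_parts,
        },
    )


def flag_artifact_trials(panels: list[VelocityPanel],
                         factor: float = 10.0) -> dict:
    """Flag trials whose maximum per-part raw-velocity variance exceeds
    ``factor`` times the median of that statistic across trials.

    A reproducible stand-in for visual artifact screening; returns a report
    and sets ``qc_flag`` on the offending panels.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        stats = np.array([np.nanmax(np.nanvar(p.raw_velocity, axis=0)) for p in panels])
    med = float(np.median(stats))
    flags = stats > factor * med if med > 0 else np.zeros(len(panels), bool)
    for p, f in zip(panels, flags):
        p.qc_flag = p.qc_flag or bool(f)
    return {
        "n_trials": len(panels),
        "n_flagged": int(flags.sum()),
        "flagged": [p.trial_id for p, f in zip(panels, flags) if f],
        "threshold": factor * med,
        "statistic": stats.tolist(),
    }


def velocity_range(panel: VelocityPanel, pre_normalization: bool = True) -> np.ndarray:
    """Per-part velocity range (max - min over time).

    With ``pre_normalization`` (the default, and what the range analysis
    uses) this is the per-landmark range averaged within part, in
    pixels/frame; otherwise the range of the z-scored part stream.
    """
    if pre_normalization:
        return panel.part_range.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmax(panel.velocity, axis=0) - np.nanmin(panel.velocity, axis=0)
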