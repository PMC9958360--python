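"""Synthetic dyadic movement data with known ground truth.

The generator emulates the statistical structure the analysis chain
assumes: two seated participants whose body parts are mostly still, with
sparse movement *bursts* — fast-rising, slower-decaying velocity events —
riding on a small noisy baseline.  Under the coupled (by default: Vision)
conditions, each spontaneous burst of one participant triggers, with
probability ``coupling_prob``, a response burst in the partner after
``coupling_lag`` seconds (plus jitter), in a body part drawn from a
response-probability matrix.  Near trials scale burst amplitudes by a gain
factor (people move more when closer), and body parts have distinct
amplitude scales (hands fastest, torso slowest), mirroring the intra-personal
velocity-range structure of seated face-to-face interaction.

Two output levels are available:

* ``landmarks`` — full 67-landmark coordinate series (with injected missing
  samples and outlier spikes) that exercise the I/O and preprocessing
  stages; bursts displace all member landmarks of a part coherently along a
  random direction in the image plane;
* ``velocity`` — body-part velocity panels generated directly from the same
  burst process, the fast path for study-scale statistical experiments.

Every dataset carries a :class:`SyntheticTruth` recording the planted events
and coupling, so downstream estimates can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .landmarks import (
    CONDITIONS, LANDMARK_NAMES, PART_NAMES, LandmarkSeries, TrialManifest,
    default_grouping,
)
from .permstats import StudyVelocities
from .preprocess import VelocityPanel, zscore

#: Default per-part burst amplitude scale (peak burst velocity,
#: pixels/frame), ordered like PART_NAMES.  Hands move most, torso least,
#: as for seated spontaneous movement.
DEFAULT_PART_SCALE: tuple[float, ...] = (
    0.6,   # Head
    0.4,   # Torso
    0.8,   # LeftArm
    1.4,   # LeftHand
    0.8,   # RightArm
    2.6,   # RightHand
    0.5,   # LeftKnee
    0.5,   # RightKnee
    1.0,   # LeftFoot
    1.0,   # RightFoot
)


def uniform_response_matrix() -> np.ndarray:
    """Response part drawn uniformly: synchrony spreads over all
    combinations, not only homologous ones."""
    n = len(PART_NAMES)
    return np.full((n, n), 1.0 / n)


def homologous_response_matrix() -> np.ndarray:
    """Mimicry-style preset: responses land in the same body part."""
    return np.eye(len(PART_NAMES))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the defaults are the emulated study layout
    (23 dyads, 3 trials per condition cell, 120-s trials at 30 Hz)."""

    n_dyads: int = 23
    trials_per_condition: int = 3
    duration: float = 120.0          # seconds
    frame_rate: float = 30.0         # Hz
    burst_rate: float = 3.0          # spontaneous events/min per body part
    burst_rise: float = 0.1          # seconds to peak
    burst_decay: float = 0.5         # decay time constant, seconds
    amplitude_sigma: float = 0.4     # lognormal sigma of burst amplitudes
    part_scale: tuple[float, ...] = DEFAULT_PART_SCALE
    coupling_prob: float = 0.8
    coupling_lag: float = 0.2        # seconds
    lag_jitter: float = 0.05         # SD of lag jitter, seconds
    coupled_conditions: tuple[tuple[str, str], ...] = (
        ("Far", "Vision"), ("Near", "Vision"))
    bidirectional_coupling: bool = True  # False: only participant 0 leads
    cross_part_matrix: tuple[tuple[float, ...], ...] = field(
        default_factory=lambda: tuple(map(tuple, uniform_response_matrix())))
    proximity_amplitude_gain: float = 1.5
    baseline_sd: float = 0.05        # baseline velocity noise scale
    missing_frac: float = 0.08       # fraction of zero-confidence samples
    outlier_frac: float = 0.0068     # fraction of spiked samples
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.coupling_prob <= 1:
            raise ValueError("coupling_prob must be in [0, 1]")
        if self.coupling_lag >= self.duration:
            raise ValueError("coupling_lag must be shorter than the trial")
        for name in ("duration", "frame_rate", "burst_rate", "burst_rise",
                     "burst_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.missing_frac < 1 or not 0 <= self.outlier_frac < 1:
            raise ValueError("corruption fractions must be in [0, 1)")
        m = np.asarray(self.cross_part_matrix, dtype=float)
        if m.shape != (len(PART_NAMES),) * 2 or (m < 0).any():
            raise ValueError("cross_part_matrix must be a nonnegative 10x10 matrix")
        if not np.allclose(m.sum(axis=1), 1.0):
            raise ValueError("cross_part_matrix rows must sum to 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated trial.

    ``events[p]`` lists, for participant ``p`` in {0, 1}, tuples
    ``(time_s, part_index, amplitude, kind)`` with kind ``"spont"`` or
    ``"response"``; ``responses`` lists
    ``(stim_participant, stim_time, stim_part, resp_part, realized_lag)``.
    """

    condition: tuple[str, str]
    coupled: bool
    events: tuple[list, list] = field(default_factory=lambda: ([], []))
    responses: list = field(default_factory=list)
    corruption: dict = field(default_factory=dict)

    def validate(self) -> None:
        for stim_p, t, _sp, _rp, lag in self.responses:
            if lag < 0:
                raise ValueError("realized response lags must be nonnegative")
            if stim_p not in (0, 1):
                raise ValueError("stimulus participant must be 0 or 1")


def burst_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Unit-peak velocity kernel: fast saturating rise, exponential decay.

    ``k(t) = c * (1 - exp(-t/rise)) * exp(-t/decay)`` for t >= 0, normalised
    to peak 1; rise < decay gives the positively skewed, fast-rising burst
    profile of spontaneous movements.
    """
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0) / rise))
                 * np.exp(-np.maximum(t, 0) / decay), 0.0)
    t_peak = rise * np.log(1.0 + decay / rise)
    peak = (1.0 - np.exp(-t_peak / rise)) * np.exp(-t_peak / decay)
    return k / peak


def _draw_events(cfg: SyntheticConfig, condition: tuple[str, str],
                 rng: np.random.Generator) -> SyntheticTruth:
    """Draw spontaneous and response burst events for both participants."""
    coupled = tuple(condition) in {tuple(c) for c in cfg.coupled_conditions}
    gain = cfg.proximity_amplitude_gain if condition[0] == "Near" else 1.0
    cross = np.asarray(cfg.cross_part_matrix, dtype=float)
    truth = SyntheticTruth(condition=tuple(condition), coupled=coupled)

    # Coupling changes *when* people move, not how much: with responses
    # switched on, spontaneous rates are thinned so the expected total event
    # rate (spontaneous + responses) matches the uncoupled rate.  Visual
    # contact therefore leaves intra-personal movement quantity untouched.
    base_rate = cfg.burst_rate / 60.0  # events per second per part
    if coupled and cfg.coupling_prob > 0:
        if cfg.bidirectional_coupling:
            spont_rate = [base_rate / (1 + cfg.coupling_prob)] * 2
        else:
            spont_rate = [base_rate, base_rate * (1 - cfg.coupling_prob)]
    else:
        spont_rate = [base_rate, base_rate]

    spont = []
    for p in (0, 1):
        for part in range(len(PART_NAMES)):
            rate = spont_rate[p]
            n_ev = rng.poisson(rate * cfg.duration)
            times = np.sort(rng.uniform(0, cfg.duration, size=n_ev))
            for t in times:
                amp = gain * cfg.part_scale[part] * rng.lognormal(0.0, cfg.amplitude_sigma)
                truth.events[p].append((float(t), part, float(amp), "spont"))
                spont.append((p, float(t), part))
    if coupled and cfg.coupling_prob > 0:
        for p, t, part in spont:
            if not cfg.bidirectional_coupling and p != 0:
                continue
            if rng.random() >= cfg.coupling_prob:
                continue
            lag = max(0.0, cfg.coupling_lag + cfg.lag_jitter * rng.standard_normal())
            t_resp = t + lag
            if t_resp >= cfg.duration:
                continue
            other = 1 - p
            resp_part = int(rng.choice(len(PART_NAMES), p=cross[part]))
            amp = gain * cfg.part_scale[resp_part] * rng.lognormal(0.0, cfg.amplitude_sigma)
            truth.events[other].append((float(t_resp), resp_part, float(amp), "response"))
            truth.responses.append((p, float(t), part, resp_part, float(lag)))
    truth.validate()
    return truth


def _part_velocity_from_events(cfg: SyntheticConfig, events: list,
                               rng: np.random.Generator) -> np.ndarray:
    """Superpose burst kernels (plus smooth nonnegative baseline noise) into
    a (frames, 10) nonnegative part-velocity array."""
    n = cfg.n_frames
    t = np.arange(n) / cfg.frame_rate
    v = np.zeros((n, len(PART_NAMES)))
    span = cfg.burst_rise + 6 * cfg.burst_decay
    for t0, part, amp, _kind in events:
        i0 = max(0, int(np.floor(t0 * cfg.frame_rate)))
        i1 = min(n, int(np.ceil((t0 + span) * cfg.frame_rate)) + 1)
        v[i0:i1, part] += amp * burst_kernel(t[i0:i1] - t0, cfg.burst_rise,
                                             cfg.burst_decay)
    # smooth strictly-positive baseline: AR(1) noise pushed through softplus
    v += cfg.baseline_sd * np.log1p(np.exp(_ar1(n, len(PART_NAMES), 0.95, rng)))
    return v


def _ar1(n: int, m: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance AR(1) noise, shape (n, m)."""
    e = rng.standard_normal((n, m))
    e[1:] *= np.sqrt(1 - phi ** 2)
    return lfilter([1.0], [1.0, -phi], e, axis=0)


def generate_velocity_trial(cfg: SyntheticConfig, condition: tuple[str, str],
                            rng: np.random.Generator
                            ) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Fast path: raw (nonnegative) part-velocity arrays for both
    participants, shape ``(frames, 10)`` each, plus ground truth."""
    truth = _draw_events(cfg, condition, rng)
    va = _part_velocity_from_events(cfg, truth.events[0], rng)
    vb = _part_velocity_from_events(cfg, truth.events[1], rng)
    return va, vb, truth


# ---------------------------------------------------------------------------
# landmark-level generation
# ---------------------------------------------------------------------------

def _rest_skeleton(rng: np.random.Generator) -> np.ndarray:
    """Plausible rest positions (pixels) for a seated person in a 1280x720
    frame; hands get small per-landmark offsets around the wrist."""
    base = {
        "Nose": (640, 200), "Neck": (640, 260), "MidHip": (640, 480),
        "RHip": (600, 480), "LHip": (680, 480),
        "RShoulder": (580, 270), "RElbow": (545, 360), "RWrist": (540, 440),
        "LShoulder": (700, 270), "LElbow": (735, 360), "LWrist": (740, 440),
        "RKnee": (580, 560), "LKnee": (700, 560),
        "RAnkle": (575, 650), "LAnkle": (705, 650),
        "REye": (625, 190), "LEye": (655, 190),
        "REar": (610, 200), "LEar": (670, 200),
        "RBigToe": (565, 680), "RSmallToe": (555, 678), "RHeel": (585, 672),
        "LBigToe": (715, 680), "LSmallToe": (725, 678), "LHeel": (695, 672),
    }
    coords = np.zeros((len(LANDMARK_NAMES), 2))
    for i, name in enumerate(LANDMARK_NAMES):
        if name in base:
            coords[i] = base[name]
        elif name.startswith("LHand"):
            coords[i] = np.array(base["LWrist"]) + rng.uniform(-15, 15, 2)
        else:
            coords[i] = np.array(base["RWrist"]) + rng.uniform(-15, 15, 2)
    coords += rng.uniform(-5, 5, coords.shape)  # person-specific variation
    return coords


def _landmark_series_from_events(cfg: SyntheticConfig, events: list,
                                 participant_id: str, trial_id: str,
                                 rng: np.random.Generator) -> LandmarkSeries:
    n = cfg.n_frames
    t = np.arange(n) / cfg.frame_rate
    grouping = default_grouping()
    part_idx = grouping.indices(LANDMARK_NAMES)
    coords = np.broadcast_to(_rest_skeleton(rng), (n, len(LANDMARK_NAMES), 2)).copy()

    # integrated burst displacement: all member landmarks move coherently;
    # amplitudes are peak velocities in px/frame, so displacement is the
    # plain per-frame cumulative sum
    span = cfg.burst_rise + 6 * cfg.burst_decay
    for t0, part, amp, _kind in events:
        members = part_idx[PART_NAMES[part]]
        theta = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(theta), np.sin(theta)])
        i0 = max(0, int(np.floor(t0 * cfg.frame_rate)))
        i1 = min(n, int(np.ceil((t0 + span) * cfg.frame_rate)) + 1)
        vel = amp * burst_kernel(t[i0:i1] - t0, cfg.burst_rise, cfg.burst_decay)
        disp = np.cumsum(vel)  # px; the part drifts then stays
        coords[i0:i1, members[:, None], np.arange(2)] += \
            disp[:, None, None] * direction
        if i1 < n:
            coords[i1:, members[:, None], np.arange(2)] += disp[-1] * direction

    # positional jitter: slow AR(1), per landmark and axis
    jitter = _ar1(n, len(LANDMARK_NAMES) * 2, 0.9, rng)
    coords += 0.3 * jitter.reshape(n, len(LANDMARK_NAMES), 2)

    confidence = np.clip(rng.normal(0.85, 0.08, (n, len(LANDMARK_NAMES))), 0.05, 1.0)
    corruption = {}
    if cfg.missing_frac > 0:
        miss = rng.random((n, len(LANDMARK_NAMES))) < cfg.missing_frac
        confidence[miss] = 0.0
        coords[miss] = np.nan
        corruption["missing_mask_count"] = int(miss.sum())
    if cfg.outlier_frac > 0:
        spike = rng.random((n, len(LANDMARK_NAMES))) < cfg.outlier_frac
        spike &= confidence > 0
        mag = rng.uniform(80, 200, (n, len(LANDMARK_NAMES), 2)) \
            * rng.choice([-1.0, 1.0], (n, len(LANDMARK_NAMES), 2))
        coords[spike] += mag[spike]
        corruption["outlier_mask_count"] = int(spike.sum())
    series = LandmarkSeries(participant_id=participant_id, trial_id=trial_id,
                            frame_rate=cfg.frame_rate, coords=coords,
                            confidence=confidence)
    series._corruption = corruption  # attached for truth bookkeeping
    return series


def generate_dyad_trial(cfg: SyntheticConfig, condition: tuple[str, str],
                        rng: np.random.Generator,
                        dyad_id: str = "dyad01", trial_id: str = "t01"
                        ) -> tuple[LandmarkSeries, LandmarkSeries, SyntheticTruth]:
    """Landmark-level generation of one dyad trial under one condition."""
    truth = _draw_events(cfg, condition, rng)
    a = _landmark_series_from_events(cfg, truth.events[0], f"{dyad_id}a",
                                     trial_id, rng)
    b = _landmark_series_from_events(cfg, truth.events[1], f"{dyad_id}b",
                                     trial_id, rng)
    truth.corruption = {
        "a": getattr(a, "_corruption", {}),
        "b": getattr(b, "_corruption", {}),
    }
    return a, b, truth


# ---------------------------------------------------------------------------
# whole-study generation
# ---------------------------------------------------------------------------

def study_manifest(cfg: SyntheticConfig) -> list[TrialManifest]:
    """Full study layout: every dyad runs ``trials_per_condition`` trials
    in each of the four condition cells."""
    rows = []
    for d in range(cfg.n_dyads):
        dyad = f"dyad{d + 1:02d}"
        idx = 0
        for block in range(1, cfg.trials_per_condition + 1):
            for prox, vis in CONDITIONS:
                idx += 1
                rows.append(TrialManifest(
                    dyad_id=dyad, participant_a=f"{dyad}a", participant_b=f"{dyad}b",
                    proximity=prox, vision=vis, block=block, trial_index=idx,
                    duration=cfg.duration))
    return rows


def _raw_to_panel(raw: np.ndarray) -> np.ndarray:
    """Z-score raw part velocities into analysis panels (velocity level)."""
    return zscore(raw, axis=0)


def generate_study(cfg: SyntheticConfig, level: str = "velocity",
                   rng: np.random.Generator | None = None):
    """Generate a full study.

    ``level="velocity"`` (fast path for statistical experiments) returns a
    :class:`~imsync.permstats.StudyVelocities` whose ``raw_ranges`` carry the
    per-participant part velocity ranges per condition (for the range
    ANOVA), with per-trial ground truth under ``truth``.

    ``level="landmarks"`` yields ``(manifest, data, truths)`` where ``data``
    maps ``(dyad_id, trial_index)`` to the two landmark series.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    manifest = study_manifest(cfg)
    if level == "landmarks":
        data, truths = {}, {}
        for row in manifest:
            a, b, truth = generate_dyad_trial(
                cfg, row.condition, rng, dyad_id=row.dyad_id,
                trial_id=f"{row.dyad_id}_t{row.trial_index:02d}")
            data[(row.dyad_id, row.trial_index)] = (a, b)
            truths[(row.dyad_id, row.trial_index)] = truth
        return manifest, data, truths
    if level != "velocity":
        raise ValueError("level must be 'velocity' or 'landmarks'")

    cond_index = {tuple(c): i for i, c in enumerate(CONDITIONS)}
    dyad_ids = [f"dyad{d + 1:02d}" for d in range(cfg.n_dyads)]
    trials = [[[] for _ in CONDITIONS] for _ in dyad_ids]
    raw_ranges: dict = {}
    truths: dict = {}
    for row in manifest:
        d = dyad_ids.index(row.dyad_id)
        c = cond_index[row.condition]
        va, vb, truth = generate_velocity_trial(cfg, row.condition, rng)
        trials[d][c].append((_raw_to_panel(va), _raw_to_panel(vb)))
        rng_a = np.ptp(va, axis=0)
        rng_b = np.ptp(vb, axis=0)
        raw_ranges.setdefault((row.dyad_id, row.condition), []).append(
            np.stack([rng_a, rng_b]))
        truths[(row.dyad_id, row.trial_index)] = truth
    study = StudyVelocities(dyad_ids=dyad_ids, trials=trials,
                            raw_ranges=raw_ranges, truth=truths)
    study.validate()
    return study


def range_table_from_study(study: StudyVelocities) -> "pd.DataFrame":
    """Tidy velocity-range table (dyad, proximity, vision, part, range) from
    a velocity-level study: ranges averaged across trials of a condition and
    across the two participants."""
    import pandas as pd

    if not study.raw_ranges:
        raise ValueError("study carries no raw velocity ranges")
    rows = []
    for (dyad, (prox, vis)), per_trial in study.raw_ranges.items():
        mean_range = np.mean(np.stack(per_trial), axis=(0, 1))  # trials, participants
        for p, part in enumerate(PART_NAMES):
            rows.append({"dyad": dyad, "proximity": prox, "vision": vis,
                         "part": part, "range": float(mean_range[p])})
    return pd.DataFrame(rows)


def velocity_panel_from_raw(raw: np.ndarray, participant_id: str, trial_id: str,
                            frame_rate: float) -> VelocityPanel:
    """Wrap a raw synthetic part-velocity array in a VelocityPanel (velocity
    level bypasses the landmark preprocessing chain)."""
    return VelocityPanel(
        participant_id=participant_id, trial_id=trial_id, frame_rate=frame_rate,
        part_names=PART_NAMES, velocity=_raw_to_panel(raw), raw_velocity=raw,
        part_range=np.ptp(raw, axis=0), provenance={"synthetic": True},
    )
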