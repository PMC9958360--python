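"""Pose-landmark containers, keypoint I/O and the landmark -> body-part grouping.

The expected input is the standard 2-D pose-estimation output for a seated
person filmed by a single camera: 25 body landmarks (BODY_25 layout) plus 21
landmarks per hand, each carrying pixel coordinates ``(x, y)`` and a detection
confidence in ``[0, 1]``.  Coordinates are raw pixels in the camera frame
(0-based, y growing downward); no calibration is applied anywhere downstream,
so velocities are expressed in pixels/frame.

Missing detections are represented by ``NaN`` coordinates together with zero
confidence — the convention used by the pose library itself, which emits
``x = y = c = 0`` for landmarks it could not place.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: BODY_25 landmark names in model output order.
BODY25_NAMES: tuple[str, ...] = (
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip", "RHip",
    "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe",
    "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel",
)

LEFT_HAND_NAMES: tuple[str, ...] = tuple(f"LHand{i:02d}" for i in range(21))
RIGHT_HAND_NAMES: tuple[str, ...] = tuple(f"RHand{i:02d}" for i in range(21))

#: Full 67-landmark layout: 25 body + 21 left hand + 21 right hand.
LANDMARK_NAMES: tuple[str, ...] = BODY25_NAMES + LEFT_HAND_NAMES + RIGHT_HAND_NAMES

#: The ten analysed body parts, in fixed output order.
PART_NAMES: tuple[str, ...] = (
    "Head", "Torso", "LeftArm", "LeftHand", "RightArm",
    "RightHand", "LeftKnee", "RightKnee", "LeftFoot", "RightFoot",
)

PROXIMITY_LEVELS: tuple[str, ...] = ("Far", "Near")
VISION_LEVELS: tuple[str, ...] = ("NoVision", "Vision")

#: The four condition cells of the 2x2 design, in fixed order
#: (proximity slow axis, vision fast axis).
CONDITIONS: tuple[tuple[str, str], ...] = (
    ("Far", "NoVision"), ("Far", "Vision"),
    ("Near", "NoVision"), ("Near", "Vision"),
)


class SchemaError(ValueError):
    """A table or file does not match the expected layout."""


@dataclass
class LandmarkSeries:
    """Raw keypoint trajectories for one participant in one trial.

    ``coords`` has shape ``(frames, n_landmarks, 2)`` and ``confidence``
    shape ``(frames, n_landmarks)``.  A sample is *missing* when its
    confidence is 0 (equivalently its coordinates are NaN).
    """

    participant_id: str
    trial_id: str
    frame_rate: float
    coords: np.ndarray
    confidence: np.ndarray
    landmark_names: tuple[str, ...] = LANDMARK_NAMES

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError(f"coords must be (frames, landmarks, 2), got {self.coords.shape}")
        if self.confidence.shape != self.coords.shape[:2]:
            raise ValueError("confidence and coords disagree on (frames, landmarks)")
        if len(self.landmark_names) != self.coords.shape[1]:
            raise ValueError("landmark_names length does not match coords")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        finite = np.isfinite(self.confidence)
        if np.any((self.confidence[finite] < 0) | (self.confidence[finite] > 1)):
            raise ValueError("confidence values must lie in [0, 1]")
        # normalise the missing sentinel: zero confidence <-> NaN coordinates
        missing = ~finite | (self.confidence == 0) | ~np.isfinite(self.coords).all(axis=2)
        self.coords[missing] = np.nan
        self.confidence[missing] = 0.0

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(frames, landmarks)`` mask of missing samples."""
        return self.confidence == 0

    def copy(self) -> "LandmarkSeries":
        return replace(self, coords=self.coords.copy(), confidence=self.confidence.copy())


@dataclass(frozen=True)
class TrialManifest:
    """One row of the study manifest: which dyad/trial/condition a recording is."""

    dyad_id: str
    participant_a: str
    participant_b: str
    proximity: str
    vision: str
    block: int
    trial_index: int
    duration: float = 120.0

    def __post_init__(self) -> None:
        if self.proximity not in PROXIMITY_LEVELS:
            raise ValueError(f"proximity must be one of {PROXIMITY_LEVELS}")
        if self.vision not in VISION_LEVELS:
            raise ValueError(f"vision must be one of {VISION_LEVELS}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def condition(self) -> tuple[str, str]:
        return (self.proximity, self.vision)


@dataclass(frozen=True)
class BodyPartGrouping:
    """Mapping from the ten analysed body parts to their member landmarks.

    The hand groups always hold the 21 hand landmarks each and the knees a
    single landmark.  The head/torso split of the remaining trunk landmarks is
    configuration: the shipped default places Neck with the head (``Head`` =
    Nose, LEye, REye, Neck; ``Torso`` = MidHip, LHip, RHip), and
    :func:`default_grouping` can alternatively assign Neck to the torso.
    Landmarks not claimed by any group (the ears, by default) are dropped with
    a logged notice.
    """

    parts: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.parts) != set(PART_NAMES):
            raise ValueError(f"grouping must define exactly the parts {PART_NAMES}")
        seen: set[str] = set()
        for part, members in self.parts.items():
            if len(members) == 0:
                raise ValueError(f"part {part!r} has no member landmarks")
            for name in members:
                if name not in LANDMARK_NAMES:
                    raise ValueError(f"unknown landmark {name!r} in part {part!r}")
                if name in seen:
                    raise ValueError(f"landmark {name!r} assigned to more than one part")
                seen.add(name)

    def members(self, part: str) -> tuple[str, ...]:
        return self.parts[part]

    def indices(self, landmark_names: tuple[str, ...] | None = None) -> dict[str, np.ndarray]:
        """Member column indices per part, for a given landmark ordering."""
        names = list(landmark_names or LANDMARK_NAMES)
        return {
            part: np.array([names.index(m) for m in members], dtype=int)
            for part, members in self.parts.items()
        }

    @property
    def used_landmarks(self) -> set[str]:
        return {m for members in self.parts.values() for m in members}


def default_grouping(neck_group: str = "Head") -> BodyPartGrouping:
    """The shipped landmark -> body-part mapping.

    Parameters
    ----------
    neck_group:
        Which group receives the Neck landmark, ``"Head"`` (default) or
        ``"Torso"``.  Neck belongs to exactly one group.
    """
    if neck_group not in ("Head", "Torso"):
        raise ValueError("neck_group must be 'Head' or 'Torso'")
    head = ["Nose", "LEye", "REye"]
    torso = ["MidHip", "LHip", "RHip"]
    (head if neck_group == "Head" else torso).append("Neck")
    parts = {
        "Head": tuple(head),
        "Torso": tuple(torso),
        "LeftArm": ("LShoulder", "LElbow", "LWrist"),
        "LeftHand": LEFT_HAND_NAMES,
        "RightArm": ("RShoulder", "RElbow", "RWrist"),
        "RightHand": RIGHT_HAND_NAMES,
        "LeftKnee": ("LKnee",),
        "RightKnee": ("RKnee",),
        "LeftFoot": ("LAnkle", "LBigToe", "LSmallToe", "LHeel"),
        "RightFoot": ("RAnkle", "RBigToe", "RSmallToe", "RHeel"),
    }
    grouping = BodyPartGrouping(parts)
    unused = sorted(set(LANDMARK_NAMES) - grouping.used_landmarks)
    if unused:
        logger.info("landmarks not assigned to any body part (dropped): %s", unused)
    return grouping


# ---------------------------------------------------------------------------
# per-frame keypoint JSON (pose-library dialect)
# ---------------------------------------------------------------------------

_JSON_FIELDS = (
    ("pose_keypoints_2d", 25),
    ("hand_left_keypoints_2d", 21),
    ("hand_right_keypoints_2d", 21),
)


def _frame_from_person(person: dict, where: str) -> tuple[np.ndarray, np.ndarray]:
    xs, cs = [], []
    for key, n in _JSON_FIELDS:
        flat = np.asarray(person.get(key, []), dtype=float)
        if flat.size != 3 * n:
            raise SchemaError(f"{where}: field {key!r} must hold {3 * n} values, got {flat.size}")
        triplets = flat.reshape(n, 3)
        xs.append(triplets[:, :2])
        cs.append(triplets[:, 2])
    return np.concatenate(xs, axis=0), np.concatenate(cs, axis=0)


def read_keypoint_json(path: str | Path, frame_rate: float,
                       participant_id: str = "", trial_id: str = "",
                       person_index: int | None = None) -> LandmarkSeries:
    """Read per-frame keypoint JSON into a :class:`LandmarkSeries`.

    ``path`` is either a directory of per-frame ``*.json`` files (sorted by
    name, i.e. by frame index when zero-padded) or a single JSON file holding
    a list of frame objects.  Each frame object has a ``people`` list whose
    entries carry flat ``[x, y, c]`` triplets under ``pose_keypoints_2d``,
    ``hand_left_keypoints_2d`` and ``hand_right_keypoints_2d``.

    Exactly one detected person per frame is expected; with several people a
    ``person_index`` must be supplied.  Zero-confidence keypoints come out as
    missing samples.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.json"))
        if not files:
            raise FileNotFoundError(f"no JSON frame files under {path}")
        frames = []
        for f in files:
            try:
                frames.append(json.loads(f.read_text()))
            except json.JSONDecodeError as exc:
                raise SchemaError(f"malformed JSON in frame file {f.name}: {exc}") from exc
        labels = [f.name for f in files]
    else:
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"malformed JSON in {path}: {exc}") from exc
        if not isinstance(data, list):
            raise SchemaError(f"{path}: expected a list of frame objects")
        frames = data
        labels = [f"frame {i}" for i in range(len(frames))]

    coords, confs = [], []
    for label, frame in zip(labels, frames):
        people = frame.get("people", [])
        if len(people) == 0:
            coords.append(np.full((len(LANDMARK_NAMES), 2), np.nan))
            confs.append(np.zeros(len(LANDMARK_NAMES)))
            continue
        if len(people) > 1 and person_index is None:
            raise SchemaError(f"{label}: {len(people)} people detected but no person_index given")
        person = people[person_index or 0]
        xy, c = _frame_from_person(person, label)
        coords.append(xy)
        confs.append(c)
    return LandmarkSeries(
        participant_id=participant_id or path.stem,
        trial_id=trial_id or path.stem,
        frame_rate=frame_rate,
        coords=np.stack(coords),
        confidence=np.stack(confs),
    )


def write_keypoint_json(series: LandmarkSeries, path: str | Path) -> Path:
    """Write a series as a single JSON file of per-frame objects (round-trips
    with :func:`read_keypoint_json`; missing samples become 0/0/0 triplets)."""
    path = Path(path)
    out = []
    for t in range(series.n_frames):
        xy = np.nan_to_num(series.coords[t], nan=0.0)
        c = series.confidence[t]
        flat = np.concatenate([xy, c[:, None]], axis=1)
        person = {}
        start = 0
        for key, n in _JSON_FIELDS:
            person[key] = flat[start:start + n].ravel().tolist()
            start += n
        out.append({"people": [person]})
    path.write_text(json.dumps(out))
    return path


# ---------------------------------------------------------------------------
# long-format tabular I/O
# ---------------------------------------------------------------------------

_TABULAR_COLUMNS = ["frame", "landmark", "x", "y", "confidence"]


def write_tabular(series: LandmarkSeries, path: str | Path) -> Path:
    """Write a series as a long-format CSV with columns
    ``frame, landmark, x, y, confidence`` (deterministic row/column order)."""
    path = Path(path)
    n_f, n_l = series.n_frames, series.n_landmarks
    df = pd.DataFrame({
        "frame": np.repeat(np.arange(n_f), n_l),
        "landmark": np.tile(np.asarray(series.landmark_names, dtype=object), n_f),
        "x": series.coords[:, :, 0].ravel(),
        "y": series.coords[:, :, 1].ravel(),
        "confidence": series.confidence.ravel(),
    })
    df.to_csv(path, index=False)
    return path


def read_tabular(path: str | Path, frame_rate: float,
                 participant_id: str = "", trial_id: str = "") -> LandmarkSeries:
    """Read a long-format CSV (see :func:`write_tabular`) into a series."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in _TABULAR_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing required columns {missing_cols}")
    if len(df) == 0:
        raise SchemaError(f"{path}: table is empty")
    landmarks = list(dict.fromkeys(df["landmark"]))  # first-appearance order
    n_l = len(landmarks)
    frames = np.sort(df["frame"].unique())
    n_f = len(frames)
    if len(df) != n_f * n_l:
        raise SchemaError(f"{path}: expected {n_f * n_l} rows (frames x landmarks), got {len(df)}")
    col = {name: i for i, name in enumerate(landmarks)}
    row = {f: i for i, f in enumerate(frames)}
    coords = np.full((n_f, n_l, 2), np.nan)
    conf = np.zeros((n_f, n_l))
    i = df["frame"].map(row).to_numpy()
    j = df["landmark"].map(col).to_numpy()
    coords[i, j, 0] = df["x"].to_numpy()
    coords[i, j, 1] = df["y"].to_numpy()
    conf[i, j] = df["confidence"].to_numpy()
    return LandmarkSeries(
        participant_id=participant_id or path.stem,
        trial_id=trial_id or path.stem,
        frame_rate=frame_rate,
        coords=coords,
        confidence=conf,
        landmark_names=tuple(landmarks),
    )


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

def write_manifest(rows: list[TrialManifest], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([vars(r) for r in rows])
    df.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> list[TrialManifest]:
    df = pd.read_csv(path)
    required = {"dyad_id", "participant_a", "participant_b", "proximity",
                "vision", "block", "trial_index"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: manifest missing columns {sorted(missing)}")
    rows = []
    for rec in df.to_dict("records"):
        rows.append(TrialManifest(
            dyad_id=str(rec["dyad_id"]),
            participant_a=str(rec["participant_a"]),
            participant_b=str(rec["participant_b"]),
            proximity=rec["proximity"],
            vision=rec["vision"],
            block=int(rec["block"]),
            trial_index=int(rec["trial_index"]),
            duration=float(rec.get("duration", 120.0)),
        ))
    return rows
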