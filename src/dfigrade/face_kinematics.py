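"""Landmark geometry and per-region movement-amplitude extraction.

The grading method quantifies how far each facial landmark travels from its
resting position during a standardized movement task, separately for the
forehead, eye region, and mouth, and separately for the subject's left and
right hemiface.  Head motion is confounded with facial motion in raw
coordinates, so every frame is rigidly aligned (Kabsch least-squares
superposition) to the neutral frame using the midline landmarks — which are
assumed stationary relative to the skull — before displacements are measured.

Coordinates are millimetres in a right-handed, subject-centric frame
("left" means the subject's anatomical left).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    MIDLINE = "midline"


class Region(str, enum.Enum):
    FOREHEAD = "forehead"
    EYE = "eye"
    MOUTH = "mouth"
    OTHER = "other"


class TaskName(str, enum.Enum):
    """The nine standardized training movements; three of them double as the
    diagnostic grimaces (one per region)."""

    EYEBROW_ELEVATION = "eyebrow_elevation"
    EYE_CLOSURE = "eye_closure"
    CHEEK_INFLATION = "cheek_inflation"
    LIP_PURSING = "lip_pursing"
    MOUTH_LATERAL_RIGHT = "mouth_lateral_right"
    MOUTH_LATERAL_LEFT = "mouth_lateral_left"
    MOUTH_OPEN_WIDE = "mouth_open_wide"
    MOUTH_CORNER_ELEVATION = "mouth_corner_elevation"
    SHOW_TEETH = "show_teeth"


#: Region each movement task probes.
TASK_REGION: dict[TaskName, Region] = {
    TaskName.EYEBROW_ELEVATION: Region.FOREHEAD,
    TaskName.EYE_CLOSURE: Region.EYE,
    TaskName.CHEEK_INFLATION: Region.MOUTH,
    TaskName.LIP_PURSING: Region.MOUTH,
    TaskName.MOUTH_LATERAL_RIGHT: Region.MOUTH,
    TaskName.MOUTH_LATERAL_LEFT: Region.MOUTH,
    TaskName.MOUTH_OPEN_WIDE: Region.MOUTH,
    TaskName.MOUTH_CORNER_ELEVATION: Region.MOUTH,
    TaskName.SHOW_TEETH: Region.MOUTH,
}

#: Diagnostic grimace set: one task per region.
DIAGNOSTIC_BATTERY: tuple[TaskName, ...] = (
    TaskName.EYEBROW_ELEVATION,
    TaskName.EYE_CLOSURE,
    TaskName.SHOW_TEETH,
)

TRAINING_BATTERY: tuple[TaskName, ...] = tuple(TaskName)

#: Default capture window in seconds.
DEFAULT_WINDOW_S = 5.0


class KinematicsError(ValueError):
    """Domain error raised by landmark-geometry operations."""


@dataclass(frozen=True)
class Landmark:
    """A named facial landmark with side and region labels."""

    id: str
    side: Side
    region: Region


@dataclass(frozen=True)
class MovementTask:
    name: TaskName
    region: Region

    def __post_init__(self) -> None:
        expected = TASK_REGION[self.name]
        if self.region != expected:
            raise KinematicsError(
                f"task {self.name.value} probes region {expected.value}, "
                f"not {self.region.value}"
            )

    @classmethod
    def from_name(cls, name: TaskName | str) -> "MovementTask":
        name = TaskName(name)
        return cls(name=name, region=TASK_REGION[name])


@dataclass
class LandmarkFrame:
    """Landmark positions (mm) at one time point."""

    t: float
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.t < 0:
            raise KinematicsError(f"frame time must be >= 0, got {self.t}")
        clean = {}
        for lid, xyz in self.positions.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,):
                raise KinematicsError(f"landmark {lid!r}: expected 3D coordinate")
            if not np.all(np.isfinite(arr)):
                raise KinematicsError(f"landmark {lid!r}: non-finite coordinate")
            clean[lid] = arr
        self.positions = clean


@dataclass
class MovementRecording:
    """One movement task: a neutral (rest) frame plus a time-ordered frame
    sequence over the capture window."""

    task: MovementTask
    neutral: LandmarkFrame
    frames: list[LandmarkFrame]
    landmarks: list[Landmark]
    duration: float = DEFAULT_WINDOW_S

    def __post_init__(self) -> None:
        if not self.frames:
            raise KinematicsError("recording has no frames")
        if self.duration <= 0:
            raise KinematicsError("duration must be > 0")
        times = [f.t for f in self.frames]
        if any(b < a for a, b in zip(times, times[1:])):
            raise KinematicsError("frames are not time-ordered")
        ids = set(self.neutral.positions)
        declared = {lm.id for lm in self.landmarks}
        if ids != declared:
            missing = sorted(ids ^ declared)
            raise KinematicsError(
                f"landmark declarations and neutral frame disagree on ids: {missing}"
            )
        for fr in self.frames:
            if set(fr.positions) != ids:
                raise KinematicsError(
                    "inconsistent landmark set: frame at "
                    f"t={fr.t} does not match the neutral frame"
                )

    @property
    def landmark_map(self) -> dict[str, Landmark]:
        return {lm.id: lm for lm in self.landmarks}


@dataclass(frozen=True)
class RegionAmplitude:
    """Movement amplitude (mm) of one region on one hemiface."""

    region: Region
    side: Side
    amplitude: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.amplitude) or self.amplitude < 0:
            raise KinematicsError(
                f"amplitude must be finite and >= 0, got {self.amplitude}"
            )


def mirror_pairs(landmarks: Iterable[Landmark]) -> list[tuple[str, str]]:
    """Pair each left landmark with its right mirror partner.

    Pairing is by shared base identifier with the trailing side tag stripped
    (``browL``/``browR`` or ``brow_left``/``brow_right``).  Midline landmarks
    are excluded.  Raises :class:`KinematicsError` naming any unpaired
    non-midline landmark.
    """
    def base(lid: str, side: Side) -> str:
        for suffix in (side.value.capitalize(), "_" + side.value, side.value[0].upper()):
            if lid.endswith(suffix):
                return lid[: -len(suffix)]
        return lid

    left: dict[str, Landmark] = {}
    right: dict[str, Landmark] = {}
    for lm in landmarks:
        if lm.side == Side.MIDLINE:
            continue
        bucket = left if lm.side == Side.LEFT else right
        bucket[base(lm.id, lm.side)] = lm

    pairs: list[tuple[str, str]] = []
    for key in sorted(left):
        if key not in right:
            raise KinematicsError(f"unpaired landmark: {left[key].id}")
        lm_l, lm_r = left[key], right[key]
        if lm_l.region != lm_r.region:
            raise KinematicsError(
                f"mirror pair {lm_l.id}/{lm_r.id} spans regions "
                f"{lm_l.region.value}/{lm_r.region.value}"
            )
        pairs.append((lm_l.id, lm_r.id))
    unpaired_right = set(right) - set(left)
    if unpaired_right:
        lid = right[sorted(unpaired_right)[0]].id
        raise KinematicsError(f"unpaired landmark: {lid}")
    return pairs


def _kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of `moving` onto `target` (n x 3).

    Returns (R, t) with target ≈ moving @ R.T + t.
    """
    mu_m = moving.mean(axis=0)
    mu_t = target.mean(axis=0)
    H = (moving - mu_m).T @ (target - mu_t)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_m
    return R, t


def align_frame_to_neutral(
    frame: LandmarkFrame,
    neutral: LandmarkFrame,
    landmark_map: Mapping[str, Landmark],
) -> LandmarkFrame:
    """Rigidly align a frame to the neutral frame using midline landmarks.

    With fewer than 3 midline landmarks the superposition is underdetermined
    and the frame is returned unchanged.
    """
    midline_ids = sorted(
        lid for lid, lm in landmark_map.items() if lm.side == Side.MIDLINE
    )
    if len(midline_ids) < 3:
        return frame
    moving = np.array([frame.positions[lid] for lid in midline_ids])
    target = np.array([neutral.positions[lid] for lid in midline_ids])
    R, t = _kabsch(moving, target)
    aligned = {lid: R @ p + t for lid, p in frame.positions.items()}
    return LandmarkFrame(t=frame.t, positions=aligned)


def extract_region_amplitude(
    recording: MovementRecording,
    region: Region | str,
    side: Side | str,
    *,
    align: bool = True,
) -> RegionAmplitude:
    """Movement amplitude (mm) of one region-side landmark set.

    Per landmark, the maximum Euclidean displacement from its neutral-frame
    position across all frames (after rigid midline alignment of each frame
    to the neutral frame); the amplitude is the mean of these per-landmark
    maxima.
    """
    region = Region(region)
    side = Side(side)
    if side == Side.MIDLINE:
        raise KinematicsError("amplitude is defined for left/right hemifaces only")
    lmap = recording.landmark_map
    ids = sorted(
        lid for lid, lm in lmap.items() if lm.region == region and lm.side == side
    )
    if not ids:
        raise KinematicsError(
            f"empty region: no landmarks with region={region.value}, side={side.value}"
        )
    neutral_pos = np.array([recording.neutral.positions[lid] for lid in ids])
    max_disp = np.zeros(len(ids))
    for fr in recording.frames:
        if align:
            fr = align_frame_to_neutral(fr, recording.neutral, lmap)
        pos = np.array([fr.positions[lid] for lid in ids])
        disp = np.linalg.norm(pos - neutral_pos, axis=1)
        np.maximum(max_disp, disp, out=max_disp)
    return RegionAmplitude(region=region, side=side, amplitude=float(max_disp.mean()))


def extract_all_amplitudes(
    recording: MovementRecording, *, align: bool = True
) -> list[RegionAmplitude]:
    """Amplitudes of the task's region for both hemifaces."""
    return [
        extract_region_amplitude(recording, recording.task.region, side, align=align)
        for side in (Side.LEFT, Side.RIGHT)
    ]
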