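from __future__ import annotations

import numpy as np
import pytest

from dfigrade.face_kinematics import (
    Landmark,
    LandmarkFrame,
    MovementRecording,
    MovementTask,
    Region,
    Side,
    TaskName,
)


def make_recording(
    task: TaskName = TaskName.SHOW_TEETH,
    displacements: dict[str, list[np.ndarray]] | None = None,
    landmarks: list[Landmark] | None = None,
    neutral_positions: dict[str, np.ndarray] | None = None,
    n_frames: int = 5,
    duration: float = 5.0,
) -> MovementRecording:
    """Hand-built recording: per-landmark displacement paths around a default
    two-landmark mouth + three-midline-anchor face."""
    if landmarks is None:
        landmarks = [
            Landmark("mouthL", Side.LEFT, Region.MOUTH),
            Landmark("mouthR", Side.RIGHT, Region.MOUTH),
            Landmark("noseTip", Side.MIDLINE, Region.OTHER),
            Landmark("chin", Side.MIDLINE, Region.OTHER),
            Landmark("foreheadMid", Side.MIDLINE, Region.OTHER),
        ]
    if neutral_positions is None:
        neutral_positions = {
            "mouthL": np.array([20.0, -30.0, 50.0]),
            "mouthR": np.array([-20.0, -30.0, 50.0]),
            "noseTip": np.array([0.0, 0.0, 65.0]),
            "chin": np.array([0.0, -55.0, 45.0]),
            "foreheadMid": np.array([0.0, 60.0, 50.0]),
        }
    displacements = displacements or {}
    times = np.linspace(0.0, duration, n_frames)
    frames = []
    for idx, t in enumerate(times):
        pos = {}
        for lid, p0 in neutral_positions.items():
            d = displacements.get(lid)
            pos[lid] = p0 + (d[idx] if d is not None else 0.0)
        frames.append(LandmarkFrame(t=float(t), positions=pos))
    return MovementRecording(
        task=MovementTask.from_name(task),
        neutral=LandmarkFrame(t=0.0, positions=dict(neutral_positions)),
        frames=frames,
        landmarks=landmarks,
        duration=duration,
    )


@pytest.fixture
def still_recording() -> MovementRecording:
    """All frames identical to the neutral frame."""
    return make_recording()


@pytest.fixture
def toy_rater_table() -> np.ndarray:
    return np.array([[7, 8, 9], [5, 5, 6], [2, 3, 2], [9, 9, 10]], dtype=float)
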