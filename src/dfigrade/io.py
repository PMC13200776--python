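"""Readers and writers for recordings, rater tables, and result reports.

Recording JSON schema::

    {"task": "<task name>", "duration_s": 5.0,
     "landmarks": [{"id": "...", "side": "left|right|midline",
                    "region": "forehead|eye|mouth|other"}, ...],
     "neutral": {"t": 0.0, "positions": {"<id>": [x, y, z], ...}},
     "frames": [{"t": 0.2, "positions": {...}}, ...]}

Also accepted: long-format CSV with columns task, frame_index, t,
landmark_id, side, region, x, y, z where frame_index −1 denotes the neutral
frame.  Coordinates are millimetres; CSV files are UTF-8, comma-separated,
with a header row and "." as the decimal separator.  Percentages are stored
as numbers on the 0–100 scale.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .agreement_stats import RaterTable
from .dfi_scoring import DFIResult
from .face_kinematics import (
    Landmark,
    LandmarkFrame,
    MovementRecording,
    MovementTask,
    Region,
    Side,
)


class ParseError(ValueError):
    """Malformed input file; message names the offending field."""


def read_recording(path: str | Path) -> MovementRecording:
    """Read a movement recording from JSON or long-format CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_recording_csv(path)
    return _read_recording_json(path)


def _read_recording_json(path: Path) -> MovementRecording:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    for key in ("task", "landmarks", "frames"):
        if key not in doc:
            raise ParseError(f"{path}: missing field {key!r}")
    if "neutral" not in doc:
        raise ParseError(f"{path}: missing neutral frame")
    try:
        task = MovementTask.from_name(doc["task"])
    except ValueError as exc:
        raise ParseError(f"{path}: unknown task {doc['task']!r}") from exc
    try:
        landmarks = [
            Landmark(id=lm["id"], side=Side(lm["side"]), region=Region(lm["region"]))
            for lm in doc["landmarks"]
        ]
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: bad landmark entry ({exc})") from exc

    def frame(obj: dict, what: str) -> LandmarkFrame:
        if "positions" not in obj:
            raise ParseError(f"{path}: {what} missing 'positions'")
        return LandmarkFrame(
            t=float(obj.get("t", 0.0)),
            positions={k: np.asarray(v, dtype=float) for k, v in obj["positions"].items()},
        )

    return MovementRecording(
        task=task,
        neutral=frame(doc["neutral"], "neutral frame"),
        frames=[frame(f, f"frame {i}") for i, f in enumerate(doc["frames"])],
        landmarks=landmarks,
        duration=float(doc.get("duration_s", 5.0)),
    )


_CSV_COLUMNS = ["task", "frame_index", "t", "landmark_id", "side", "region", "x", "y", "z"]


def _read_recording_csv(path: Path) -> MovementRecording:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    tasks = df["task"].unique()
    if len(tasks) != 1:
        raise ParseError(f"{path}: expected one task per file, found {list(tasks)}")
    task = MovementTask.from_name(str(tasks[0]))
    lm_info = df.drop_duplicates("landmark_id")
    landmarks = [
        Landmark(id=str(r.landmark_id), side=Side(r.side), region=Region(r.region))
        for r in lm_info.itertuples()
    ]

    def frame_of(group: pd.DataFrame) -> LandmarkFrame:
        return LandmarkFrame(
            t=float(max(group["t"].iloc[0], 0.0)),
            positions={
                str(r.landmark_id): np.array([r.x, r.y, r.z], dtype=float)
                for r in group.itertuples()
            },
        )

    if -1 not in df["frame_index"].values:
        raise ParseError(f"{path}: missing neutral frame (frame_index -1)")
    neutral = frame_of(df[df["frame_index"] == -1])
    frames = [
        frame_of(g)
        for _, g in df[df["frame_index"] >= 0].sort_values("frame_index").groupby(
            "frame_index", sort=True
        )
    ]
    duration = float(df.loc[df["frame_index"] >= 0, "t"].max()) or 5.0
    return MovementRecording(
        task=task, neutral=neutral, frames=frames, landmarks=landmarks, duration=duration
    )


def write_recording(recording: MovementRecording, path: str | Path) -> None:
    """Write a recording as JSON (loss-free round trip with read_recording)."""
    doc = {
        "task": recording.task.name.value,
        "duration_s": recording.duration,
        "landmarks": [
            {"id": lm.id, "side": lm.side.value, "region": lm.region.value}
            for lm in recording.landmarks
        ],
        "neutral": _frame_doc(recording.neutral),
        "frames": [_frame_doc(f) for f in recording.frames],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def _frame_doc(frame: LandmarkFrame) -> dict:
    return {"t": frame.t, "positions": {k: list(v) for k, v in frame.positions.items()}}


_SCALE_BOUNDS = {"SI": (0, 10), "HBS": (1, 6), "SFGS": (0, 100), "DFI": (0, 100)}


def read_table(path: str | Path, scale: str | None = None) -> RaterTable:
    """Read a subjects × measurements CSV (first column = subject id).

    If ``scale`` names one of the four scales, values are range-checked
    against that scale's legal raw range.
    """
    if scale is not None and scale not in _SCALE_BOUNDS:
        raise ParseError(
            f"unknown scale {scale!r}; expected one of {sorted(_SCALE_BOUNDS)}"
        )
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: need a subject-id column plus >= 2 measurement columns")
    df = df.set_index(df.columns[0])
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().sum() > df[col].isna().sum():
            raise ParseError(f"{path}: non-numeric value in column {col!r}")
        df[col] = bad
        if scale is not None:
            lo, hi = _SCALE_BOUNDS[scale]
            out = bad.dropna()
            if ((out < lo) | (out > hi)).any():
                raise ParseError(
                    f"{path}: column {col!r} has a value outside the "
                    f"{scale} range [{lo}, {hi}]"
                )
    return RaterTable.from_dataframe(df, scale=scale)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str, bool)):
        return obj.value  # enums
    return obj


def dfi_result_doc(result: DFIResult) -> dict:
    """JSON-ready document mirroring the DFI result (composite to 1 dp)."""
    return {
        "dfi_percent": round(result.dfi_percent, 1),
        "dfi_percent_full": result.dfi_percent,
        "affected_side": result.ratios.affected_side.value,
        "ratios": {
            "forehead": result.ratios.forehead,
            "eye": result.ratios.eye,
            "mouth": result.ratios.mouth,
        },
        "weights": {
            "forehead": result.weights.forehead,
            "eye": result.weights.eye,
            "mouth": result.weights.mouth,
        },
        "per_region_amplitudes_mm": [
            {"region": a.region.value, "side": a.side.value, "amplitude": a.amplitude}
            for a in result.per_region_amplitudes
        ],
        "tasks_used": [t.name.value for t in result.tasks_used],
    }


def write_report(report: Any, path: str | Path) -> None:
    """Serialize a report object (dataclass, dict, DFIResult) as JSON."""
    doc = dfi_result_doc(report) if isinstance(report, DFIResult) else _jsonable(report)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def read_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_manifest(out_dir: str | Path, *, subcommand: str, inputs: list[str],
                   config: dict, seed: int | None) -> Path:
    """Record inputs, configuration, seed, and tool version for a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "dfigrade",
        "version": __version__,
        "subcommand": subcommand,
        "inputs": [str(p) for p in inputs],
        "config": _jsonable(config),
        "seed": seed,
    }
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return path
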