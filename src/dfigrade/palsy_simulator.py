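"""Synthetic facial-palsy data with known ground truth.

Two generators:

* :func:`simulate_recording` builds 3D landmark recordings for one movement
  task on a canonical, mirror-symmetric face.  Landmarks of the task's
  region follow a half-sine activation over the capture window; the healthy
  side peaks at a configurable displacement (default 8 mm) and the affected
  side at that displacement times the planted per-region severity ratio, so
  peak-excursion amplitude extraction recovers the planted ratio exactly in
  the noise-free case.
* :func:`simulate_cohort` builds a longitudinal study dataset: per-patient
  baseline facial function, exponential recovery toward 100 %, clinician
  ratings on the SI/HBS/SFGS scales (truth + rater bias + noise, then
  discretized onto each scale), and repeated instrumented measurements.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .face_kinematics import (
    DIAGNOSTIC_BATTERY,
    TRAINING_BATTERY,
    DEFAULT_WINDOW_S,
    Landmark,
    LandmarkFrame,
    MovementRecording,
    MovementTask,
    Region,
    Side,
    TaskName,
)
from .scale_conversion import ClinicalScore, Scale, from_standardized, standardize


class SimulationError(ValueError):
    pass


#: Peak displacement (mm) of a healthy hemiface during a full-effort grimace.
HEALTHY_PEAK_MM = 8.0


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth for one synthetic assessment.

    severity: planted per-region symmetry ratios (forehead, eye, mouth),
    each in [0, 1]; 1 = symmetric movement, 0 = no affected-side movement.
    """

    severity: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affected_side: Side = Side.LEFT
    landmark_noise_sd: float = 0.0
    n_frames: int = 25
    frame_rate: float | None = None
    battery: str = "diagnostic3"
    seed: int = 0
    healthy_peak_mm: float = HEALTHY_PEAK_MM
    duration: float = DEFAULT_WINDOW_S

    def __post_init__(self) -> None:
        if len(self.severity) != 3 or any(not 0 <= s <= 1 for s in self.severity):
            raise SimulationError("severity must be three ratios in [0, 1]")
        if self.affected_side == Side.MIDLINE:
            raise SimulationError("affected side must be left or right")
        if self.landmark_noise_sd < 0:
            raise SimulationError("noise SD must be >= 0")
        if self.n_frames < 2:
            raise SimulationError("need at least 2 frames")
        if self.battery not in ("diagnostic3", "training9"):
            raise SimulationError("battery must be diagnostic3 or training9")

    def severity_for(self, region: Region) -> float:
        return dict(
            zip((Region.FOREHEAD, Region.EYE, Region.MOUTH), self.severity)
        )[region]

    @property
    def tasks(self) -> tuple[TaskName, ...]:
        return DIAGNOSTIC_BATTERY if self.battery == "diagnostic3" else TRAINING_BATTERY


# Canonical landmark set: a stylized face in mm, midline x = 0, y up, z out.
# Three landmarks per region per side plus four midline anchors (enough for
# rigid alignment).
def _canonical_landmarks() -> tuple[list[Landmark], dict[str, np.ndarray]]:
    spec: list[tuple[str, Region, float, float, float]] = [
        # (base id, region, |x|, y, z) — mirrored to L/R
        ("browMed", Region.FOREHEAD, 18.0, 45.0, 55.0),
        ("browLat", Region.FOREHEAD, 40.0, 42.0, 48.0),
        ("foreheadPt", Region.FOREHEAD, 28.0, 60.0, 52.0),
        ("lidUpper", Region.EYE, 30.0, 30.0, 52.0),
        ("lidLower", Region.EYE, 30.0, 22.0, 52.0),
        ("eyeOuter", Region.EYE, 45.0, 26.0, 45.0),
        ("mouthCorner", Region.MOUTH, 26.0, -30.0, 50.0),
        ("lipUpper", Region.MOUTH, 12.0, -25.0, 55.0),
        ("lipLower", Region.MOUTH, 12.0, -38.0, 53.0),
        ("cheek", Region.OTHER, 40.0, -5.0, 48.0),
    ]
    landmarks: list[Landmark] = []
    positions: dict[str, np.ndarray] = {}
    for base, region, x, y, z in spec:
        for side, sign in ((Side.LEFT, +1.0), (Side.RIGHT, -1.0)):
            lid = base + ("L" if side == Side.LEFT else "R")
            landmarks.append(Landmark(id=lid, side=side, region=region))
            positions[lid] = np.array([sign * x, y, z])
    for lid, y, z in (
        ("noseTip", 0.0, 65.0),
        ("noseBridge", 20.0, 55.0),
        ("chin", -55.0, 45.0),
        ("foreheadMid", 62.0, 50.0),
    ):
        landmarks.append(Landmark(id=lid, side=Side.MIDLINE, region=Region.OTHER))
        positions[lid] = np.array([0.0, y, z])
    return landmarks, positions


#: Unit direction each region moves during its tasks (away from rest).
_REGION_DIRECTION = {
    Region.FOREHEAD: np.array([0.0, 1.0, 0.0]),     # brow raise: upward
    Region.EYE: np.array([0.0, -0.8, 0.6]) / np.linalg.norm([0.0, -0.8, 0.6]),
    Region.MOUTH: np.array([0.6, 0.8, 0.0]) / np.linalg.norm([0.6, 0.8, 0.0]),
}


def simulate_recording(
    config: SimulationConfig, task: MovementTask | TaskName | str
) -> MovementRecording:
    """One synthetic movement recording with planted per-region severity.

    The healthy hemiface's landmarks of the task's region travel along a
    half-sine activation peaking at ``healthy_peak_mm``; the affected side
    peaks at ``healthy_peak_mm × severity[region]``.  Isotropic Gaussian
    noise of ``landmark_noise_sd`` mm is added to every non-neutral frame.
    The seed is mixed with the task name so each task in a battery gets
    independent noise while the whole battery stays reproducible.
    """
    if not isinstance(task, MovementTask):
        task = MovementTask.from_name(task)
    landmarks, neutral_pos = _canonical_landmarks()
    lmap = {lm.id: lm for lm in landmarks}

    task_seed = (config.seed * 131 + list(TaskName).index(task.name)) % (2**31)
    rng = np.random.default_rng(task_seed)

    severity = config.severity_for(task.region)
    direction = _REGION_DIRECTION[task.region]
    times = np.linspace(0.0, config.duration, config.n_frames)

    frames: list[LandmarkFrame] = []
    for t in times:
        activation = math.sin(math.pi * t / config.duration)
        positions: dict[str, np.ndarray] = {}
        for lid, p0 in neutral_pos.items():
            lm = lmap[lid]
            if lm.region == task.region and lm.side != Side.MIDLINE:
                peak = config.healthy_peak_mm
                if lm.side == config.affected_side:
                    peak *= severity
                # mirror the lateral component so motion stays symmetric
                d = direction.copy()
                if lm.side == Side.RIGHT:
                    d[0] = -d[0]
                p = p0 + peak * activation * d
            else:
                p = p0.copy()
            if config.landmark_noise_sd > 0:
                p = p + rng.normal(0.0, config.landmark_noise_sd, size=3)
            positions[lid] = p
        frames.append(LandmarkFrame(t=float(t), positions=positions))

    return MovementRecording(
        task=task,
        neutral=LandmarkFrame(t=0.0, positions={k: v.copy() for k, v in neutral_pos.items()}),
        frames=frames,
        landmarks=landmarks,
        duration=config.duration,
    )


def simulate_battery(config: SimulationConfig) -> list[MovementRecording]:
    """All recordings of the configured battery (3 diagnostic or 9 training
    tasks)."""
    return [simulate_recording(config, name) for name in config.tasks]


def planted_dfi(config: SimulationConfig) -> float:
    """The composite the planted severities imply: 100×(0.1 r_f + 0.4 r_e + 0.5 r_m)."""
    r_f, r_e, r_m = config.severity
    return 100.0 * (0.1 * r_f + 0.4 * r_e + 0.5 * r_m)


@dataclass(frozen=True)
class CohortConfig:
    """Longitudinal study generator: n patients, visits in days, blinded
    raters with bias and noise, repeated instrumented measurements."""

    n_patients: int = 30
    visit_days: tuple[float, ...] = (0.0, 28.0)
    baseline_mean: float = 40.0          # % intact function at symptom onset
    baseline_sd: float = 15.0
    recovery_rate_shape: float = 4.0     # Gamma shape of per-patient rate
    recovery_rate_mean: float = 0.08     # per day; ~90 % of deficit gone by day 28
    n_raters: int = 3
    rater_bias_sd: float = 3.0           # percent points, fixed per rater
    rater_noise_sd: float = 5.0          # percent points, per rating
    rater_biases: tuple[float, ...] | None = None
    dfi_noise_sd: float = 5.0            # percent points, per capture
    dfi_bias: float = 0.0                # planted systematic optimism
    n_dfi_measurements: int = 3
    scales: tuple[Scale, ...] = (Scale.SI, Scale.HBS, Scale.SFGS)
    discretize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise SimulationError("need at least 1 patient")
        if any(b <= a for a, b in zip(self.visit_days, self.visit_days[1:])):
            raise SimulationError("visit days must be increasing")
        if self.baseline_sd < 0 or self.rater_noise_sd < 0 or self.dfi_noise_sd < 0:
            raise SimulationError("SDs must be >= 0")
        if self.recovery_rate_mean <= 0 or self.recovery_rate_shape <= 0:
            raise SimulationError("recovery-rate parameters must be > 0")
        if self.rater_biases is not None and len(self.rater_biases) != self.n_raters:
            raise SimulationError("rater_biases length must equal n_raters")


def _rate_scale_on(scale: Scale, percent: float, discretize: bool) -> float:
    """Standardized (0–100) value a rater reports on a given scale for a
    perceived function level, including the scale's discretization."""
    percent = float(np.clip(percent, 0.0, 100.0))
    if not discretize or scale in (Scale.SFGS, Scale.DFI):
        # SFGS treated as effectively continuous (integer 0-100 grid)
        value = round(percent) if discretize else percent
        return float(value)
    raw = from_standardized(percent, scale)
    return standardize(raw).percent


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate the longitudinal rating dataset.

    Returns a tidy DataFrame with one row per patient × visit carrying the
    latent truth, per-rater standardized scores for each clinician scale,
    per-rater raw values, and the repeated instrumented (DFI) captures.
    """
    rng = np.random.default_rng(config.seed % (2**31))

    if config.rater_biases is not None:
        biases = np.asarray(config.rater_biases, dtype=float)
    else:
        biases = rng.normal(0.0, config.rater_bias_sd, size=config.n_raters)

    baselines = np.clip(
        rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_patients),
        0.0,
        100.0,
    )
    rates = rng.gamma(
        config.recovery_rate_shape,
        config.recovery_rate_mean / config.recovery_rate_shape,
        size=config.n_patients,
    )

    rows = []
    for i in range(config.n_patients):
        for day in config.visit_days:
            truth = 100.0 - (100.0 - baselines[i]) * math.exp(-rates[i] * day)
            row: dict[str, object] = {
                "patient_id": f"p{i + 1:03d}",
                "visit_day": day,
                "truth_percent": truth,
            }
            for scale in config.scales:
                for j in range(config.n_raters):
                    perceived = truth + biases[j] + rng.normal(0.0, config.rater_noise_sd)
                    std = _rate_scale_on(scale, perceived, config.discretize)
                    key = f"rater{j + 1}_{scale.value.lower()}"
                    row[key] = std
                    if scale in (Scale.SI, Scale.HBS):
                        row[key + "_raw"] = from_standardized(std, scale).value
            for m in range(config.n_dfi_measurements):
                dfi = truth + config.dfi_bias + rng.normal(0.0, config.dfi_noise_sd)
                row[f"dfi_rep{m + 1}"] = float(np.clip(dfi, 0.0, 100.0))
            row["dfi"] = row["dfi_rep1"]
            rows.append(row)
    return pd.DataFrame(rows)
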