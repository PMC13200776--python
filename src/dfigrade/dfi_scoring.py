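"""Digital Facial Index: contralateral normalization and the weighted composite.

For each facial region the affected hemiface's movement amplitude is divided
by the contralateral (healthy) amplitude, giving a symmetry ratio in [0, 1].
The three regional ratios are combined with fixed weights — forehead 10 %,
eye region 40 %, mouth 50 % — into a composite percentage where 100 % is
intact facial function and 0 % is complete paresis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .face_kinematics import (
    DIAGNOSTIC_BATTERY,
    KinematicsError,
    MovementRecording,
    MovementTask,
    Region,
    RegionAmplitude,
    Side,
    extract_region_amplitude,
)


class ScoringError(ValueError):
    """Domain error raised by DFI scoring operations."""


#: Amplitudes below this (mm) are treated as "no evaluable motion".
DEAD_ZONE_MM = 0.5

#: Facial regions entering the composite, in weight order.
SCORED_REGIONS = (Region.FOREHEAD, Region.EYE, Region.MOUTH)


@dataclass(frozen=True)
class DFIWeights:
    """Fixed regional weighting of the composite index."""

    forehead: float = 0.10
    eye: float = 0.40
    mouth: float = 0.50

    def __post_init__(self) -> None:
        if min(self.forehead, self.eye, self.mouth) <= 0:
            raise ScoringError("weights must be positive")
        if abs(self.forehead + self.eye + self.mouth - 1.0) > 1e-12:
            raise ScoringError("weights must sum to 1")

    def __getitem__(self, region: Region) -> float:
        return {
            Region.FOREHEAD: self.forehead,
            Region.EYE: self.eye,
            Region.MOUTH: self.mouth,
        }[region]


@dataclass(frozen=True)
class SymmetryRatios:
    """Per-region affected/contralateral amplitude ratios, clipped to [0, 1]."""

    forehead: float
    eye: float
    mouth: float
    affected_side: Side

    def __post_init__(self) -> None:
        for name in ("forehead", "eye", "mouth"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ScoringError(f"{name} ratio {v} outside [0, 1]")
        if self.affected_side == Side.MIDLINE:
            raise ScoringError("affected side must be left or right")

    def __getitem__(self, region: Region) -> float:
        return {
            Region.FOREHEAD: self.forehead,
            Region.EYE: self.eye,
            Region.MOUTH: self.mouth,
        }[region]


@dataclass(frozen=True)
class DFIResult:
    ratios: SymmetryRatios
    weights: DFIWeights
    dfi_percent: float
    per_region_amplitudes: tuple[RegionAmplitude, ...]
    tasks_used: tuple[MovementTask, ...]

    def __post_init__(self) -> None:
        expected = 100.0 * (
            self.weights.forehead * self.ratios.forehead
            + self.weights.eye * self.ratios.eye
            + self.weights.mouth * self.ratios.mouth
        )
        if abs(self.dfi_percent - expected) > 1e-9:
            raise ScoringError("dfi_percent inconsistent with ratios and weights")


def compute_symmetry_ratio(
    affected_amplitude: float,
    contralateral_amplitude: float,
    *,
    dead_zone_mm: float = DEAD_ZONE_MM,
) -> float:
    """Affected/contralateral amplitude ratio, clipped to [0, 1].

    If both amplitudes fall below the dead zone there is no evaluable motion
    and the movement is treated as symmetric (ratio 1.0); if only the
    affected side falls below, the region is fully paretic (ratio 0.0).
    """
    if affected_amplitude < 0 or contralateral_amplitude < 0:
        raise ScoringError("amplitudes must be >= 0")
    if affected_amplitude < dead_zone_mm and contralateral_amplitude < dead_zone_mm:
        return 1.0
    if affected_amplitude < dead_zone_mm:
        return 0.0
    if contralateral_amplitude < dead_zone_mm:
        return 1.0
    return min(affected_amplitude / contralateral_amplitude, 1.0)


def detect_affected_side(
    amplitudes: Iterable[RegionAmplitude],
    *,
    weights: DFIWeights | None = None,
    override: Side | str | None = None,
) -> Side:
    """Infer the paretic hemiface: the side with the smaller weighted mean
    amplitude across scored regions.  An explicit override always wins."""
    if override is not None:
        side = Side(override)
        if side == Side.MIDLINE:
            raise ScoringError("override must be left or right")
        return side
    weights = weights or DFIWeights()
    totals = {Side.LEFT: 0.0, Side.RIGHT: 0.0}
    counts = {Side.LEFT: 0, Side.RIGHT: 0}
    for amp in amplitudes:
        if amp.region not in SCORED_REGIONS:
            continue
        totals[amp.side] += weights[amp.region] * amp.amplitude
        counts[amp.side] += 1
    if counts[Side.LEFT] == 0 or counts[Side.RIGHT] == 0:
        raise ScoringError("need amplitudes for both sides of at least one region")
    if math.isclose(totals[Side.LEFT], totals[Side.RIGHT], rel_tol=0, abs_tol=1e-12):
        raise ScoringError(
            "ambiguous side: weighted amplitudes are tied; pass an explicit "
            "affected-side override"
        )
    return Side.LEFT if totals[Side.LEFT] < totals[Side.RIGHT] else Side.RIGHT


def compute_dfi(
    recordings: Sequence[MovementRecording],
    affected_side: Side | str | None = None,
    *,
    weights: DFIWeights | None = None,
    dead_zone_mm: float = DEAD_ZONE_MM,
) -> DFIResult:
    """Compute the composite index from a battery of movement recordings.

    The battery must probe all three regions (the 3-grimace diagnostic set is
    the minimum; the full 9-task battery is pooled).  Regions probed by
    several tasks use the mean of per-task ratios.  If ``affected_side`` is
    not given it is inferred from the amplitudes.
    """
    weights = weights or DFIWeights()
    if not recordings:
        raise ScoringError("incomplete task battery: no recordings")

    per_task: list[tuple[Region, RegionAmplitude, RegionAmplitude]] = []
    all_amps: list[RegionAmplitude] = []
    tasks: list[MovementTask] = []
    for rec in recordings:
        region = rec.task.region
        amp_l = extract_region_amplitude(rec, region, Side.LEFT)
        amp_r = extract_region_amplitude(rec, region, Side.RIGHT)
        per_task.append((region, amp_l, amp_r))
        all_amps.extend([amp_l, amp_r])
        tasks.append(rec.task)

    covered = {region for region, _, _ in per_task}
    missing = [r.value for r in SCORED_REGIONS if r not in covered]
    if missing:
        raise ScoringError(f"incomplete task battery: missing regions {missing}")

    side = detect_affected_side(all_amps, weights=weights, override=affected_side)

    ratio_lists: dict[Region, list[float]] = {r: [] for r in SCORED_REGIONS}
    for region, amp_l, amp_r in per_task:
        affected = amp_l if side == Side.LEFT else amp_r
        contra = amp_r if side == Side.LEFT else amp_l
        ratio_lists[region].append(
            compute_symmetry_ratio(
                affected.amplitude, contra.amplitude, dead_zone_mm=dead_zone_mm
            )
        )

    region_ratio = {r: sum(v) / len(v) for r, v in ratio_lists.items()}
    ratios = SymmetryRatios(
        forehead=region_ratio[Region.FOREHEAD],
        eye=region_ratio[Region.EYE],
        mouth=region_ratio[Region.MOUTH],
        affected_side=side,
    )
    dfi = 100.0 * (
        weights.forehead * ratios.forehead
        + weights.eye * ratios.eye
        + weights.mouth * ratios.mouth
    )
    return DFIResult(
        ratios=ratios,
        weights=weights,
        dfi_percent=dfi,
        per_region_amplitudes=tuple(all_amps),
        tasks_used=tuple(tasks),
    )


def exercise_accuracy(
    recording: MovementRecording,
    reference_amplitude: float,
    affected_side: Side | str,
) -> float:
    """Percentage feedback score for one training exercise.

    100 × min(achieved / reference, 1), where "achieved" is the affected-side
    amplitude of the task's region.
    """
    if reference_amplitude <= 0:
        raise ScoringError("reference amplitude must be > 0")
    side = Side(affected_side)
    amp = extract_region_amplitude(recording, recording.task.region, side)
    return 100.0 * min(amp.amplitude / reference_amplitude, 1.0)
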