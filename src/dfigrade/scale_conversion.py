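"""Conversion between the four facial-function scales.

All four scales are mapped onto a common standardized axis where 100 % means
fully intact facial function:

=========  ==========  =========================  ====================
scale      raw range   direction                  standardization
=========  ==========  =========================  ====================
SI         0–10        inverse (0 = normal)       (10 − SI) × 10
HBS        I–VI        inverse (I = normal)       (6 − grade) × 20
SFGS       0–100       direct                     identity
DFI        0–100       direct                     identity
=========  ==========  =========================  ====================

The linear forms reproduce the anchor DFI 60 % ↔ SI 4 ↔ HBS III ↔ SFGS 60
exactly.  Converting to a discrete scale (SI, HBS) rounds to the nearest
legal grade, with exact ties rounded toward worse function (conservative
clinical reporting).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass


class Scale(str, enum.Enum):
    SI = "SI"          # Stennert Index, 0-10, lower is better
    HBS = "HBS"        # House-Brackmann, grades I-VI, lower is better
    SFGS = "SFGS"      # Sunnybrook, 0-100, higher is better
    DFI = "DFI"        # Digital Facial Index, 0-100 %, higher is better


class ConversionError(ValueError):
    """Out-of-range score or illegal conversion request."""


_ROMAN = ["I", "II", "III", "IV", "V", "VI"]

_RANGES = {
    Scale.SI: (0, 10),
    Scale.HBS: (1, 6),
    Scale.SFGS: (0.0, 100.0),
    Scale.DFI: (0.0, 100.0),
}

#: Scales whose raw values are discrete grades.
DISCRETE_SCALES = (Scale.SI, Scale.HBS)


@dataclass(frozen=True)
class ClinicalScore:
    """A value on one of the four scales."""

    scale: Scale
    value: float

    def __post_init__(self) -> None:
        lo, hi = _RANGES[self.scale]
        if not math.isfinite(self.value) or not (lo <= self.value <= hi):
            raise ConversionError(
                f"{self.scale.value} value {self.value} outside [{lo}, {hi}]"
            )
        if self.scale in DISCRETE_SCALES and self.value != int(self.value):
            raise ConversionError(
                f"{self.scale.value} takes integer grades, got {self.value}"
            )

    def render(self) -> str:
        if self.scale == Scale.HBS:
            return render_hbs(int(self.value))
        if self.scale in DISCRETE_SCALES:
            return str(int(self.value))
        return f"{self.value:g}"


@dataclass(frozen=True)
class StandardizedScore:
    """Common 0–100 % representation; 100 = fully intact function."""

    percent: float
    source_scale: Scale

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent <= 100.0):
            raise ConversionError(f"standardized percent {self.percent} outside [0, 100]")


def render_hbs(grade: int) -> str:
    """Roman-numeral rendering of a House-Brackmann grade (1 → ``I`` … 6 → ``VI``)."""
    if not 1 <= grade <= 6:
        raise ConversionError(f"HBS grade {grade} outside I-VI")
    return _ROMAN[grade - 1]


def parse_hbs(text: str) -> int:
    """Inverse of :func:`render_hbs`; also accepts plain integers."""
    t = text.strip().upper()
    if t in _ROMAN:
        return _ROMAN.index(t) + 1
    try:
        return int(t)
    except ValueError:
        raise ConversionError(f"not an HBS grade: {text!r}") from None


def standardize(score: ClinicalScore) -> StandardizedScore:
    """Map a raw score onto the common 0–100 % intact-function axis."""
    if score.scale == Scale.SI:
        pct = (10.0 - score.value) * 10.0
    elif score.scale == Scale.HBS:
        pct = (6.0 - score.value) * 20.0
    else:
        pct = float(score.value)
    return StandardizedScore(percent=pct, source_scale=score.scale)


def from_standardized(percent: float, target_scale: Scale) -> ClinicalScore:
    """Invert the standardization; discrete targets round to the nearest
    grade with ties toward worse function (the higher raw grade)."""
    if not (0.0 <= percent <= 100.0):
        raise ConversionError(f"percent {percent} outside [0, 100]")
    target_scale = Scale(target_scale)
    if target_scale == Scale.SI:
        raw = 10.0 - percent / 10.0
        return ClinicalScore(Scale.SI, _round_half_up(raw))
    if target_scale == Scale.HBS:
        raw = 6.0 - percent / 20.0
        return ClinicalScore(Scale.HBS, _round_half_up(raw))
    return ClinicalScore(target_scale, float(percent))


def _round_half_up(x: float) -> int:
    # Higher raw value = worse function on SI/HBS, so ties round up.
    return math.floor(x + 0.5)


def convert(score: ClinicalScore, target_scale: Scale | str) -> ClinicalScore:
    """Convert a score to another scale via the standardized axis."""
    target_scale = Scale(target_scale)
    if target_scale == score.scale:
        return score
    return from_standardized(standardize(score).percent, target_scale)
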