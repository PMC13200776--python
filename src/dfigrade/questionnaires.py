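"""Scoring of the three self-report instruments.

* FDI — Facial Disability Index: 10 items on a 1–5 response format, items
  1–5 forming the physical-function subscale and items 6–10 the
  social/well-being subscale.  Each subscale maps the item sum linearly onto
  0–100 %: percent = (sum − 5) × 5.
* SUS — System Usability Scale: 10 Likert items (1–5).  Positive items
  {1,3,5,7,9} contribute response − 1, negative items {2,4,6,8,10} contribute
  5 − response, so each contribution lies in 0–4; the composite is
  2.5 × the sum of the ten contributions.  Bands: ≥85 excellent, 70–84 good,
  50–69 acceptable, <50 poor.
* Study questionnaire — 10 Likert items (1 strongly disagree … 5 strongly
  agree) summarized per item and overall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


class QuestionnaireError(ValueError):
    pass


SUS_POSITIVE_ITEMS = (1, 3, 5, 7, 9)
SUS_NEGATIVE_ITEMS = (2, 4, 6, 8, 10)


@dataclass(frozen=True)
class FDIResponse:
    """One respondent's FDI answers; ``None`` marks a missing item."""

    physical_items: tuple[float | None, ...]
    social_items: tuple[float | None, ...]

    def __post_init__(self) -> None:
        for block in (self.physical_items, self.social_items):
            if len(block) != 5:
                raise QuestionnaireError("each FDI subscale has exactly 5 items")
            for v in block:
                if v is not None and not (1 <= v <= 5):
                    raise QuestionnaireError(f"FDI item {v} outside 1-5")


@dataclass(frozen=True)
class SUSResponse:
    items: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 10:
            raise QuestionnaireError("SUS has exactly 10 items")
        for v in self.items:
            if v is None or not (1 <= v <= 5):
                raise QuestionnaireError(f"SUS item {v} outside 1-5 or missing")


@dataclass(frozen=True)
class LikertSummary:
    item_means: tuple[float, ...]
    item_sds: tuple[float, ...]
    overall_mean: float
    overall_sd: float
    n_respondents: int


def score_fdi_subscale(items: Sequence[float | None]) -> float:
    """Score one FDI subscale (5 items, 1–5 each) as a 0–100 % value.

    A single missing item is imputed by the mean of the answered items; more
    than one missing item is refused.
    """
    if len(items) != 5:
        raise QuestionnaireError("FDI subscale has exactly 5 items")
    answered = [v for v in items if v is not None]
    for v in answered:
        if not (1 <= v <= 5):
            raise QuestionnaireError(f"FDI item {v} outside 1-5")
    if len(answered) < 4:
        raise QuestionnaireError("insufficient responses: more than 1 missing FDI item")
    if len(answered) == 4:
        answered.append(sum(answered) / 4.0)
    return (sum(answered) - 5.0) * 5.0


def score_fdi(resp: FDIResponse) -> dict[str, float]:
    """Both FDI subscale percents."""
    return {
        "physical": score_fdi_subscale(resp.physical_items),
        "social": score_fdi_subscale(resp.social_items),
    }


def sus_contributions(items: Sequence[float]) -> list[float]:
    """Per-item 0–4 contributions: response−1 for positive items, 5−response
    for (reversed) negative items."""
    if len(items) != 10:
        raise QuestionnaireError("SUS has exactly 10 items")
    out = []
    for i, v in enumerate(items, start=1):
        if v is None:
            raise QuestionnaireError(f"incomplete SUS: item {i} missing")
        if not (1 <= v <= 5):
            raise QuestionnaireError(f"SUS item {i} value {v} outside 1-5")
        out.append(v - 1.0 if i in SUS_POSITIVE_ITEMS else 5.0 - v)
    return out


def score_sus(resp: SUSResponse | Sequence[float]) -> float:
    """SUS composite: 2.5 × sum of the ten 0–4 contributions; range 0–100."""
    items = resp.items if isinstance(resp, SUSResponse) else resp
    return 2.5 * sum(sus_contributions(items))


def sus_band(score: float) -> str:
    """Usability band for a SUS composite."""
    if not (0 <= score <= 100):
        raise QuestionnaireError(f"SUS score {score} outside 0-100")
    if score >= 85:
        return "excellent"
    if score >= 70:
        return "good"
    if score >= 50:
        return "acceptable"
    return "poor"


def summarize_likert(table: pd.DataFrame | np.ndarray) -> LikertSummary:
    """Per-item mean/SD (sample SD, n−1) and the overall mean of item means
    for a respondents × items Likert table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise QuestionnaireError("expected a non-empty respondents x items table")
    if np.isnan(arr).any():
        raise QuestionnaireError("Likert table contains missing responses")
    if ((arr < 1) | (arr > 5)).any():
        raise QuestionnaireError("Likert responses must lie in 1-5")
    n = arr.shape[0]
    means = arr.mean(axis=0)
    # single respondent: SD undefined; reported as 0 (n flagged in the summary)
    sds = arr.std(axis=0, ddof=1) if n > 1 else np.zeros(arr.shape[1])
    return LikertSummary(
        item_means=tuple(float(m) for m in means),
        item_sds=tuple(float(s) for s in sds),
        overall_mean=float(means.mean()),
        overall_sd=float(means.std(ddof=1)) if arr.shape[1] > 1 else 0.0,
        n_respondents=n,
    )
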