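"""Exercise-capacity assessment and trial screening.

The 6-minute walk test (6MWT) is the standard field measure of exercise
capacity in chronic lung disease: the patient walks as far as possible in
six minutes and the total distance (and, for prescription purposes, the
fastest sustained speed) is recorded.  This module computes 6MWT summaries
from a walking-speed trace, applies the trial's eligibility screen for
COPD patients, and holds the visit-level outcome containers (CAT, mMRC,
6MWT distance) plus the 5-point Likert patient-global-assessment summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

TEST_DURATION_S = 360.0
N_SPLITS = 6

Visit = Literal["V1", "V2", "V3"]
VISIT_ORDER: tuple[Visit, ...] = ("V1", "V2", "V3")


class SixMwtResult(BaseModel):
    """Summary of one 6-minute walk test.

    ``split_speeds`` are the six per-minute mean walking speeds (m/s);
    ``max_speed`` is the fastest of the six and is the quantity the
    interactive regimen uses to set its initial walking intensity;
    ``distance`` is the total distance walked (m).
    """

    model_config = {"frozen": True}

    distance: float = Field(ge=0)
    split_speeds: tuple[float, float, float, float, float, float]
    max_speed: float = Field(gt=0)

    @field_validator("split_speeds")
    @classmethod
    def _nonnegative_splits(cls, v):
        if any(s < 0 for s in v):
            raise ValueError("split speeds must be nonnegative")
        return v

    @model_validator(mode="after")
    def _consistent(self):
        if abs(self.max_speed - max(self.split_speeds)) > 1e-9:
            raise ValueError("max_speed must equal the largest split speed")
        if abs(self.distance - 60.0 * sum(self.split_speeds)) > 1.0:
            raise ValueError("distance inconsistent with split speeds")
        return self

    @classmethod
    def from_splits(cls, split_speeds: Sequence[float]) -> "SixMwtResult":
        splits = tuple(float(s) for s in split_speeds)
        if len(splits) != N_SPLITS:
            raise ValueError(f"expected {N_SPLITS} split speeds, got {len(splits)}")
        return cls(
            distance=60.0 * sum(splits),
            split_speeds=splits,
            max_speed=max(splits),
        )


def compute_6mwt(speed_samples: Sequence[tuple[float, float]]) -> SixMwtResult:
    """Compute a :class:`SixMwtResult` from a walking-speed trace.

    Parameters
    ----------
    speed_samples
        Ordered ``(elapsed_seconds, speed_m_per_s)`` pairs covering the
        full test window ``[0, 360]`` s.  The trace is treated as piecewise
        linear between samples; per-minute split speeds are the
        time-weighted mean speed over each minute, the distance is the
        integral of speed over the six minutes, and the maximum walking
        speed is the largest split speed.

    Raises
    ------
    ValueError
        If the trace is empty, unsorted, contains negative speeds, or does
        not cover the whole six minutes.
    """
    if len(speed_samples) == 0:
        raise ValueError("empty speed trace")
    t = np.asarray([s[0] for s in speed_samples], dtype=float)
    v = np.asarray([s[1] for s in speed_samples], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("speed samples must be strictly increasing in time")
    if np.any(v < 0):
        raise ValueError("speeds must be nonnegative")
    if t[0] > 0.0 or t[-1] < TEST_DURATION_S:
        raise ValueError(
            f"trace covers [{t[0]:g}, {t[-1]:g}] s; full coverage of "
            f"[0, {TEST_DURATION_S:g}] s is required"
        )

    # Insert the minute boundaries as interpolation knots so each split is
    # an exact trapezoidal integral of the piecewise-linear trace.
    bounds = np.linspace(0.0, TEST_DURATION_S, N_SPLITS + 1)
    knots = np.union1d(t[(t >= 0.0) & (t <= TEST_DURATION_S)], bounds)
    vals = np.interp(knots, t, v)
    splits = []
    for k in range(N_SPLITS):
        sel = (knots >= bounds[k]) & (knots <= bounds[k + 1])
        splits.append(np.trapezoid(vals[sel], knots[sel]) / 60.0)
    return SixMwtResult.from_splits(splits)


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def check_eligibility(
    age: float, fev1_pct_pred: float, sixmwt_distance: float
) -> EligibilityResult:
    """Screen one candidate against the trial's inclusion criteria.

    Eligible iff age > 20 years, post-bronchodilator FEV1 < 80 % of the
    predicted value, and 6MWT distance > 150 m (all strict inequalities).
    Failing criteria are enumerated in ``reasons``.
    """
    for name, val in (("age", age), ("fev1_pct_pred", fev1_pct_pred),
                      ("sixmwt_distance", sixmwt_distance)):
        if val < 0:
            raise ValueError(f"{name} must be nonnegative, got {val}")
    reasons = []
    if not age > 20:
        reasons.append("age must exceed 20 years")
    if not fev1_pct_pred < 80:
        reasons.append("FEV1 must be below 80% predicted")
    if not sixmwt_distance > 150:
        reasons.append("6MWT distance must exceed 150 m")
    return EligibilityResult(eligible=not reasons, reasons=tuple(reasons))


class OutcomeRecord(BaseModel):
    """CAT, mMRC, and 6MWT distance for one patient at one study visit.

    Visits: V1 = baseline, V2 = 6 weeks, V3 = 12 weeks.  CAT is scored
    0-40 (lower is better), mMRC 0-4 (higher = more breathless).
    """

    model_config = {"frozen": True}

    patient_id: str
    visit: Visit
    cat: int = Field(ge=0, le=40)
    mmrc: int = Field(ge=0, le=4)
    sixmwt_distance: float = Field(ge=0)


class PgaResponse(BaseModel):
    """Patient global assessment: per-question 5-point Likert scores."""

    model_config = {"frozen": True}

    patient_id: str
    scores: Mapping[str, int]

    @field_validator("scores")
    @classmethod
    def _likert(cls, v):
        for q, s in v.items():
            if not 1 <= s <= 5:
                raise ValueError(f"question {q!r}: Likert score {s} outside [1, 5]")
        return dict(v)


def summarize_pga(responses: Iterable[PgaResponse]) -> pd.DataFrame:
    """Per-question mean, SD and n over a set of PGA responses."""
    responses = list(responses)
    if not responses:
        raise ValueError("at least one PGA response is required")
    long = pd.DataFrame(
        [
            {"patient_id": r.patient_id, "question": q, "score": s}
            for r in responses
            for q, s in r.scores.items()
        ]
    )
    out = long.groupby("question")["score"].agg(mean="mean", sd="std", n="count")
    return out
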