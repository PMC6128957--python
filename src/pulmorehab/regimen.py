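"""Adaptive walking-regimen state machines for home pulmonary rehabilitation.

Two replayable engines prescribe daily walking for COPD patients:

* **Fixed regimen** — six target distances (600, 1200, 1800, 2400, 3000,
  3600 m).  A day on which the patient's accumulated distance reaches the
  current target counts as one achievement; after 14 achievements the
  target advances to the next level.

* **Interactive regimen** — twelve intensity levels expressed as walking
  speeds.  The base speed is 80 % of the maximum walking speed measured in
  a 6-minute walk test; each level scales it by a configurable fraction.
  After every session the patient reports perceived breathing difficulty on
  the modified Borg scale (0-10): three consecutive sessions at Borg <= 3
  raise the level by one, three consecutive sessions at Borg >= 7 lower it
  by one, and an intermediate score resets both streaks.  On reaching the
  top level the patient repeats the 6MWT and restarts at level 7 with a
  recomputed base speed.

Both engines are pure: every update returns a new state with an
append-only event history, so any trajectory can be replayed exactly.
The module also provides the in-session pulse-oximetry alert (SpO2 < 90 %,
debounced), metronome cadence guidance, and the trial-arm schedule
(fixed for 12 weeks, fixed then interactive with a switch after week 6,
or control with no prescription).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

from pydantic import BaseModel, Field, field_validator, model_validator

from .assessment import SixMwtResult

SPO2_ALERT_THRESHOLD = 90.0
DEFAULT_DEBOUNCE_S = 30.0
DEFAULT_STRIDE_M = 0.70
BASE_SPEED_FRACTION = 0.80  # of the 6MWT maximum walking speed

Arm = Literal["fixed", "fixed-interactive", "control"]
ARMS: tuple[Arm, ...] = ("fixed", "fixed-interactive", "control")


def _validate_borg(borg: float) -> float:
    """Modified Borg scale: {0, 0.5, 1, 1.5, ..., 10}."""
    b = float(borg)
    if not 0.0 <= b <= 10.0:
        raise ValueError(f"Borg score {b} outside [0, 10]")
    if abs(b * 2 - round(b * 2)) > 1e-9:
        raise ValueError(f"Borg score {b} is not on the 0.5-unit grid")
    return b


class WalkSession(BaseModel):
    """One walking bout: distance, duration, Borg score, vitals stream.

    ``samples`` are ordered ``(elapsed_seconds, spo2_percent,
    heart_rate_bpm)`` triples from the wearable pulse oximeter.
    """

    model_config = {"frozen": True}

    patient_id: str
    session_date: _dt.date
    distance: float = Field(ge=0, description="meters")
    duration: float = Field(gt=0, description="seconds")
    borg: Optional[float] = None
    samples: tuple[tuple[float, float, float], ...] = ()

    @field_validator("borg")
    @classmethod
    def _borg_grid(cls, v):
        return None if v is None else _validate_borg(v)

    @field_validator("samples")
    @classmethod
    def _samples_valid(cls, v):
        last_t = None
        for t, spo2, hr in v:
            if last_t is not None and t <= last_t:
                raise ValueError("sample times must be strictly increasing")
            last_t = t
            if not 0 <= spo2 <= 100:
                raise ValueError(f"SpO2 {spo2} outside [0, 100]")
            if hr <= 0:
                raise ValueError(f"heart rate {hr} must be positive")
        return v

    @property
    def mean_speed(self) -> float:
        return self.distance / self.duration


class FixedLevelTable(BaseModel):
    """Level targets for the fixed regimen: walking distances per day."""

    model_config = {"frozen": True}

    distances: tuple[float, ...] = (600.0, 1200.0, 1800.0, 2400.0, 3000.0, 3600.0)
    achievements_required: int = Field(default=14, ge=1)

    @field_validator("distances")
    @classmethod
    def _increasing(cls, v):
        if len(v) == 0:
            raise ValueError("at least one level distance is required")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("level distances must be strictly increasing")
        if v[0] <= 0:
            raise ValueError("level distances must be positive")
        return v

    @property
    def n_levels(self) -> int:
        return len(self.distances)


class InteractiveLevelTable(BaseModel):
    """Level definitions for the interactive regimen.

    ``speed_fractions`` multiply the base speed (80 % of 6MWT max speed)
    to give the prescribed speed at each level; sessions run for
    ``session_duration_min`` minutes guided by a metronome.
    """

    model_config = {"frozen": True}

    n_levels: int = Field(default=12, ge=1)
    speed_fractions: tuple[float, ...] = tuple(
        round(1.0 + 0.02 * k, 10) for k in range(12)
    )
    session_duration_min: float = Field(default=30.0, gt=0)
    reset_level: int = Field(default=7, ge=1)
    borg_up_threshold: float = 3.0
    borg_down_threshold: float = 7.0
    streak_length: int = Field(default=3, ge=1)

    @model_validator(mode="after")
    def _consistent(self):
        if len(self.speed_fractions) != self.n_levels:
            raise ValueError("speed_fractions length must equal n_levels")
        if any(f <= 0 for f in self.speed_fractions):
            raise ValueError("speed fractions must be positive")
        if any(b < a for a, b in zip(self.speed_fractions, self.speed_fractions[1:])):
            raise ValueError("speed fractions must be nondecreasing")
        if self.reset_level > self.n_levels:
            raise ValueError("reset_level cannot exceed n_levels")
        if not self.borg_down_threshold > self.borg_up_threshold:
            raise ValueError("borg_down_threshold must exceed borg_up_threshold")
        return self


@dataclass(frozen=True)
class AlertEvent:
    """A desaturation alert: SpO2 fell below the alert threshold."""

    patient_id: str
    elapsed_seconds: float
    spo2_percent: float
    kind: str = "desaturation"


@dataclass(frozen=True)
class RegimenState:
    """Immutable engine state; updates return a new state.

    ``history`` is an append-only tuple of event dicts; replaying the same
    inputs from the same initial state reproduces state and history exactly.
    """

    regimen: Literal["fixed", "interactive"]
    level: int = 1
    achievements: int = 0
    low_borg_streak: int = 0
    high_borg_streak: int = 0
    base_speed: Optional[float] = None
    retest_pending: bool = False
    history: tuple[dict, ...] = ()

    def _log(self, event: str, **info) -> "RegimenState":
        entry = {"event": event, "level": self.level, **info}
        return replace(self, history=self.history + (entry,))


# ---------------------------------------------------------------------------
# Fixed regimen
# ---------------------------------------------------------------------------

def init_fixed(table: FixedLevelTable | None = None) -> RegimenState:
    """Start the fixed regimen at level 1 (default target 600 m)."""
    table = table or FixedLevelTable()
    state = RegimenState(regimen="fixed")
    return state._log("init", regimen="fixed", target_m=table.distances[0])


def fixed_target(state: RegimenState, table: FixedLevelTable) -> float:
    """Current daily distance target in meters."""
    if state.regimen != "fixed":
        raise ValueError("state is not on the fixed regimen")
    return table.distances[state.level - 1]


def update_fixed(
    state: RegimenState,
    sessions_for_one_day: Iterable[WalkSession],
    table: FixedLevelTable | None = None,
) -> RegimenState:
    """Credit one calendar day of walking against the fixed regimen.

    The distances of all sessions sharing the day are summed; if the sum
    reaches the current level's target the day counts as one achievement
    (at most one per day).  After ``achievements_required`` achievements
    the level advances (capped at the top level) and the counter resets.
    """
    table = table or FixedLevelTable()
    if state.regimen != "fixed":
        raise ValueError("state is not on the fixed regimen")
    sessions = list(sessions_for_one_day)
    if not sessions:
        raise ValueError("at least one session is required")
    dates = {s.session_date for s in sessions}
    if len(dates) > 1:
        raise ValueError(f"sessions span multiple dates: {sorted(map(str, dates))}")
    (day,) = dates

    daily_distance = sum(s.distance for s in sessions)
    target = fixed_target(state, table)
    if daily_distance < target:
        return state._log(
            "day_below_target", date=str(day),
            distance_m=daily_distance, target_m=target,
        )

    new = replace(state, achievements=state.achievements + 1)
    new = new._log(
        "achievement", date=str(day),
        distance_m=daily_distance, target_m=target,
        achievements=new.achievements,
    )
    if new.achievements >= table.achievements_required:
        if new.level < table.n_levels:
            new = replace(new, level=new.level + 1, achievements=0)
            new = new._log(
                "level_up", date=str(day),
                target_m=table.distances[new.level - 1],
            )
        else:
            new = replace(new, achievements=0)
            new = new._log("level_cap", date=str(day))
    return new


# ---------------------------------------------------------------------------
# Interactive regimen
# ---------------------------------------------------------------------------

def init_interactive(
    result: SixMwtResult, table: InteractiveLevelTable | None = None
) -> RegimenState:
    """Start the interactive regimen from a 6MWT.

    The base speed is 80 % of the maximum walking speed recorded in the
    test; the patient starts at level 1.
    """
    table = table or InteractiveLevelTable()
    if result.max_speed <= 0:
        raise ValueError("6MWT maximum walking speed must be positive")
    base = BASE_SPEED_FRACTION * result.max_speed
    state = RegimenState(regimen="interactive", base_speed=base)
    return state._log(
        "init", regimen="interactive", base_speed=base,
        prescribed_speed=base * table.speed_fractions[0],
    )


def prescribed_speed(state: RegimenState, table: InteractiveLevelTable) -> float:
    """Walking speed prescribed at the current interactive level (m/s)."""
    if state.regimen != "interactive" or state.base_speed is None:
        raise ValueError("state is not on the interactive regimen")
    return state.base_speed * table.speed_fractions[state.level - 1]


def update_interactive(
    state: RegimenState,
    borg: float,
    table: InteractiveLevelTable | None = None,
    date: _dt.date | str | None = None,
) -> RegimenState:
    """Apply one post-session Borg score to the interactive engine.

    Borg <= up-threshold extends the low streak (and clears the high one),
    Borg >= down-threshold the converse; an intermediate score clears both.
    A completed streak of ``streak_length`` moves the level by +/-1
    (floored at 1) and clears both streaks.  Reaching the top level flags a
    6MWT re-test; further updates are rejected until :func:`apply_retest`.
    """
    table = table or InteractiveLevelTable()
    if state.regimen != "interactive":
        raise ValueError("state is not on the interactive regimen")
    if state.retest_pending:
        raise ValueError(
            "a 6MWT re-test is pending; call apply_retest before further updates"
        )
    b = _validate_borg(borg)
    info = {"borg": b}
    if date is not None:
        info["date"] = str(date)

    low, high = state.low_borg_streak, state.high_borg_streak
    if b <= table.borg_up_threshold:
        low, high = low + 1, 0
    elif b >= table.borg_down_threshold:
        low, high = 0, high + 1
    else:
        low, high = 0, 0

    new = replace(state, low_borg_streak=low, high_borg_streak=high)
    new = new._log("borg", **info, low_streak=low, high_streak=high)

    if low >= table.streak_length:
        lvl = min(new.level + 1, table.n_levels)
        new = replace(new, level=lvl, low_borg_streak=0, high_borg_streak=0)
        new = new._log("level_up", **info)
        if lvl == table.n_levels:
            new = replace(new, retest_pending=True)
            new = new._log("retest_requested", **info)
    elif high >= table.streak_length:
        lvl = max(new.level - 1, 1)
        new = replace(new, level=lvl, low_borg_streak=0, high_borg_streak=0)
        new = new._log("level_down", **info)
    return new


def apply_retest(
    state: RegimenState,
    result: SixMwtResult,
    table: InteractiveLevelTable | None = None,
) -> RegimenState:
    """Fold a repeat 6MWT into the engine after the top level was reached.

    The base speed is recomputed as 80 % of the new maximum walking speed
    and the level restarts at ``reset_level`` (default 7).
    """
    table = table or InteractiveLevelTable()
    if state.regimen != "interactive":
        raise ValueError("state is not on the interactive regimen")
    if not state.retest_pending:
        raise ValueError("no 6MWT re-test is pending")
    if result.max_speed <= 0:
        raise ValueError("6MWT maximum walking speed must be positive")
    base = BASE_SPEED_FRACTION * result.max_speed
    new = replace(
        state,
        level=table.reset_level,
        base_speed=base,
        low_borg_streak=0,
        high_borg_streak=0,
        retest_pending=False,
    )
    return new._log(
        "retest", base_speed=base,
        prescribed_speed=base * table.speed_fractions[table.reset_level - 1],
    )


# ---------------------------------------------------------------------------
# Session-level utilities
# ---------------------------------------------------------------------------

def metronome_cadence(
    prescribed_speed_ms: float, stride_length_m: float = DEFAULT_STRIDE_M
) -> float:
    """Metronome rate (steps/min) pacing the prescribed walking speed."""
    if prescribed_speed_ms <= 0:
        raise ValueError("prescribed speed must be positive")
    if stride_length_m <= 0:
        raise ValueError("stride length must be positive")
    return prescribed_speed_ms / stride_length_m * 60.0


def monitor_spo2(
    samples: Sequence[tuple],
    threshold: float = SPO2_ALERT_THRESHOLD,
    debounce: float = DEFAULT_DEBOUNCE_S,
    patient_id: str = "",
) -> list[AlertEvent]:
    """Scan an ordered SpO2 stream for desaturation alerts.

    An alert fires at the first sample strictly below ``threshold``.
    While saturation stays continuously below threshold, repeat alerts are
    suppressed for ``debounce`` seconds after the last alert; recovery to
    >= threshold re-arms the alert immediately.

    ``samples`` are ``(elapsed_seconds, spo2_percent, ...)`` tuples, e.g.
    :attr:`WalkSession.samples`.
    """
    times = [s[0] for s in samples]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("SpO2 stream must be strictly increasing in time")
    alerts: list[AlertEvent] = []
    below = False
    last_alert_t = float("-inf")
    for s in samples:
        t, spo2 = s[0], s[1]
        if spo2 < threshold:
            if not below or (t - last_alert_t) >= debounce:
                alerts.append(AlertEvent(patient_id, t, spo2))
                last_alert_t = t
            below = True
        else:
            below = False
    return alerts


def schedule_arm(
    arm: Arm, week: int, total_weeks: int = 12, switch_week: int = 7
) -> Optional[str]:
    """Active regimen for a trial arm in a given study week.

    The fixed arm walks the fixed regimen for all 12 weeks; the
    fixed-interactive arm walks fixed for weeks 1-6 and interactive for
    weeks 7-12; the control arm has no prescription (returns ``None``).
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    if not 1 <= week <= total_weeks:
        raise ValueError(f"week {week} outside [1, {total_weeks}]")
    if arm == "control":
        return None
    if arm == "fixed":
        return "fixed"
    return "fixed" if week < switch_week else "interactive"
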