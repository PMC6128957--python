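"""Telemonitoring analytics for the central patient-monitoring service.

Clinic staff reviewing home rehabilitation need three views over the
uploaded session logs: how compliant each patient is with the daily
walking prescription, which patients need closer follow-up (any in-session
SpO2 below 90 % or any session-end Borg score of 7 or more), and a
per-patient rehabilitation record over time.  Records are scoped per site:
each participating hospital sees only its own patients.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .regimen import RegimenState, WalkSession

LOW_SPO2_THRESHOLD = 90.0
HIGH_BORG_THRESHOLD = 7.0


class ComplianceSummary(BaseModel):
    model_config = {"frozen": True}

    patient_id: str
    window_start: _dt.date
    window_end: _dt.date
    prescribed_days: int = Field(ge=1)
    active_days: int = Field(ge=0)
    compliance_rate: float = Field(ge=0, le=1)
    total_distance_m: float = Field(ge=0)
    mean_borg: Optional[float] = None

    @model_validator(mode="after")
    def _consistent(self):
        if self.active_days > self.prescribed_days:
            raise ValueError("active_days cannot exceed prescribed_days")
        return self


class FlagRecord(BaseModel):
    """One patient flagged for closer monitoring, with evidence."""

    model_config = {"frozen": True}

    patient_id: str
    reason: Literal["low_spo2", "high_borg"]
    evidence: dict


def default_calendar(start: _dt.date, weeks: int = 12) -> list[_dt.date]:
    """Daily walking prescription: every day for ``weeks`` weeks."""
    return [start + _dt.timedelta(days=d) for d in range(weeks * 7)]


def compliance(
    sessions: Iterable[WalkSession],
    prescription_calendar: Sequence[_dt.date],
    patient_id: str | None = None,
) -> ComplianceSummary:
    """Day-based compliance of one patient against a prescription calendar.

    A prescribed day counts as active iff at least one session was logged
    on that date; the compliance rate is active days / prescribed days.
    """
    calendar = sorted(set(prescription_calendar))
    if not calendar:
        raise ValueError("prescription calendar must be nonempty")
    sessions = list(sessions)
    if patient_id is None:
        ids = {s.patient_id for s in sessions}
        if len(ids) > 1:
            raise ValueError("sessions belong to multiple patients; pass patient_id")
        patient_id = ids.pop() if ids else ""
    cal_set = set(calendar)
    in_window = [s for s in sessions if s.session_date in cal_set]
    active = len({s.session_date for s in in_window})
    borgs = [s.borg for s in in_window if s.borg is not None]
    return ComplianceSummary(
        patient_id=patient_id,
        window_start=calendar[0],
        window_end=calendar[-1],
        prescribed_days=len(calendar),
        active_days=active,
        compliance_rate=active / len(calendar),
        total_distance_m=sum(s.distance for s in in_window),
        mean_borg=sum(borgs) / len(borgs) if borgs else None,
    )


def flag_patients(
    sessions: Iterable[WalkSession | Mapping],
    spo2_threshold: float = LOW_SPO2_THRESHOLD,
    borg_threshold: float = HIGH_BORG_THRESHOLD,
) -> list[FlagRecord]:
    """List patients needing closer monitoring.

    Flags exactly the patients with any SpO2 sample strictly below
    ``spo2_threshold`` (reason ``low_spo2``) or any session Borg score at
    or above ``borg_threshold`` (reason ``high_borg``), one flag per
    patient per reason carrying the first offending evidence.  Raw
    mappings that fail :class:`WalkSession` validation are skipped with a
    warning rather than aborting the scan.
    """
    flagged: dict[tuple[str, str], FlagRecord] = {}
    for i, raw in enumerate(sessions):
        if isinstance(raw, WalkSession):
            sess = raw
        else:
            try:
                sess = WalkSession.model_validate(raw)
            except Exception as exc:  # malformed upload: warn, keep scanning
                warnings.warn(f"skipping malformed session record {i}: {exc}")
                continue
        key = (sess.patient_id, "low_spo2")
        if key not in flagged:
            for t, spo2, _hr in sess.samples:
                if spo2 < spo2_threshold:
                    flagged[key] = FlagRecord(
                        patient_id=sess.patient_id, reason="low_spo2",
                        evidence={"session_date": str(sess.session_date),
                                  "elapsed_seconds": t, "spo2_percent": spo2},
                    )
                    break
        key = (sess.patient_id, "high_borg")
        if key not in flagged and sess.borg is not None and sess.borg >= borg_threshold:
            flagged[key] = FlagRecord(
                patient_id=sess.patient_id, reason="high_borg",
                evidence={"session_date": str(sess.session_date),
                          "borg": sess.borg},
            )
    return list(flagged.values())


def site_view(records: pd.DataFrame, site_id: str) -> pd.DataFrame:
    """Restrict roster/report rows to one participating hospital.

    Every row must carry a ``site`` column; an unknown site yields an
    empty frame with a warning (not an error), mirroring an empty
    dashboard for a site with no enrolments.
    """
    if "site" not in records.columns:
        raise ValueError("records must carry a 'site' column")
    out = records[records["site"] == site_id]
    if out.empty and site_id not in set(records["site"]):
        warnings.warn(f"unknown site {site_id!r}: returning no records")
    return out.copy()


def pr_record(
    sessions: Sequence[WalkSession],
    state_history: Sequence[dict] | RegimenState,
) -> pd.DataFrame:
    """Per-patient rehabilitation record: level, distance, vitals over time.

    Joins the session log with the engine's event history to produce one
    row per session: date, regimen level in force that day, distance,
    duration, mean heart rate, and Borg score.  The history must be
    replayable against the sessions: every session date needs a level in
    force (i.e. an init event at or before it).
    """
    if isinstance(state_history, RegimenState):
        state_history = list(state_history.history)
    sessions = sorted(sessions, key=lambda s: s.session_date)
    cols = ["date", "level", "distance_m", "duration_s", "mean_hr", "borg"]
    if not sessions:
        return pd.DataFrame(columns=cols)

    # Level in force per dated event; events carry the pre-update level and
    # level changes are logged after, so track the latest level per date.
    dated_levels: list[tuple[_dt.date, int]] = []
    for ev in state_history:
        if "date" in ev and "level" in ev:
            dated_levels.append((_dt.date.fromisoformat(ev["date"]), ev["level"]))
    if not dated_levels:
        raise ValueError("state history carries no dated events to join on")
    dated_levels.sort(key=lambda x: x[0])

    rows = []
    for s in sessions:
        level = None
        for d, lvl in dated_levels:
            if d <= s.session_date:
                level = lvl
            else:
                break
        if level is None:
            raise ValueError(
                f"session on {s.session_date} predates the engine history"
            )
        hrs = [hr for _t, _spo2, hr in s.samples]
        rows.append({
            "date": s.session_date,
            "level": level,
            "distance_m": s.distance,
            "duration_s": s.duration,
            "mean_hr": sum(hrs) / len(hrs) if hrs else None,
            "borg": s.borg,
        })
    return pd.DataFrame(rows, columns=cols)
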