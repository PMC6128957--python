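"""Seeded synthetic COPD cohort: patients, sessions, and visit outcomes.

Every downstream component (regimen engines, monitoring analytics, trial
statistics) is exercised against this simulator, so it models exactly the
behavioural surface those components read:

* **Latent capacity** — each patient has a sustainable walking speed
  (m/s).  Completing a session multiplies capacity by ``1 +
  training_rate``, a simple multiplicative training effect.
* **Borg response** — perceived exertion rises linearly with relative
  intensity (prescribed speed / capacity): ``borg = borg_gain * intensity
  + N(0, borg_noise_sd)``, rounded to the 0.5-unit modified-Borg grid and
  clamped to [0, 10].  Linearity is the simplest monotone response that
  drives every branch of the interactive level rules.
* **Desaturation** — in-session SpO2 is ``baseline_spo2 -
  desat_propensity * intensity`` plus noise, clamped to [70, 100], so
  patients pushed beyond capacity can trip the < 90 % alert.
* **Behaviour** — a daily Bernoulli adherence draw and a weekly Bernoulli
  dropout hazard truncate the session log the way real telemonitoring
  logs are truncated.

Baseline marginals default to a moderate-COPD outpatient population:
6-minute walk distance ~ Normal(356, 98) truncated above 150 m, CAT ~
Normal(15.6, 7.8) clipped to 0-40, FEV1 %predicted ~ Normal(58.6, 15.7)
truncated below 80 (the eligibility ceiling).  Visit outcomes at 6 and 12
weeks (V2/V3) are the baseline plus a configurable additive arm effect
plus noise.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import regimen as rg
from .assessment import OutcomeRecord, SixMwtResult
from .regimen import (
    Arm,
    ARMS,
    FixedLevelTable,
    InteractiveLevelTable,
    RegimenState,
    WalkSession,
)

SIXMWT_DURATION_S = 360.0
SAMPLE_INTERVAL_S = 30.0
# Relative per-minute speed profile of a typical 6MWT: a fast first minute,
# then settling.  Mean is 1, so the profile preserves total distance.
_SIXMWT_PROFILE = np.array([1.06, 1.03, 1.00, 0.98, 0.97, 0.96])
_SIXMWT_PROFILE = _SIXMWT_PROFILE / _SIXMWT_PROFILE.mean()


class SimPatientParams(BaseModel):
    """Latent parameters of one simulated patient."""

    model_config = {"frozen": True}

    capacity: float = Field(gt=0, description="sustainable walking speed, m/s")
    training_rate: float = Field(default=0.002, ge=0,
                                 description="fractional capacity gain per session")
    borg_noise_sd: float = Field(default=1.0, ge=0)
    borg_gain: float = Field(default=5.0, gt=0,
                             description="Borg units per unit relative intensity")
    desat_propensity: float = Field(default=4.0, ge=0,
                                    description="SpO2 %-points lost per unit intensity")
    baseline_spo2: float = Field(default=96.0, le=100)
    adherence_prob: float = Field(default=0.85, ge=0, le=1)
    dropout_hazard: float = Field(default=0.02, ge=0, le=1,
                                  description="per-week dropout probability")
    speed_noise_sd: float = Field(default=0.05, ge=0)
    spo2_noise_sd: float = Field(default=0.8, ge=0)
    hr_rest: float = Field(default=80.0, gt=0)
    hr_gain: float = Field(default=45.0, ge=0,
                           description="bpm above rest per unit intensity")
    sixmwt_performance: float = Field(
        default=1.05, gt=0,
        description="mean 6MWT speed relative to sustainable capacity; the "
                    "near-maximal test typically exceeds the 30-min pace")


class SimCohortConfig(BaseModel):
    """Study conditions for a simulated three-arm 12-week trial."""

    model_config = {"frozen": True}

    n_per_arm: int = Field(default=28, ge=1)
    weeks: int = Field(default=12, ge=1)
    seed: int = 0
    sites: tuple[str, ...] = ("site-1", "site-2", "site-3", "site-4")
    start_date: _dt.date = _dt.date(2017, 5, 1)

    # Baseline marginals (moderate-COPD outpatients).
    sixmwt_mean: float = 356.0
    sixmwt_sd: float = 98.0
    sixmwt_min: float = 150.0
    cat_mean: float = 15.59
    cat_sd: float = 7.84
    fev1_mean: float = 58.59
    fev1_sd: float = 15.75
    age_mean: float = 64.0
    age_sd: float = 8.0
    male_fraction: float = 0.82

    # Additive treatment effects on visit outcomes, per arm.
    sixmwt_effect_v2: dict[str, float] = {
        "fixed": 25.0, "fixed-interactive": 25.0, "control": 0.0}
    sixmwt_effect_v3: dict[str, float] = {
        "fixed": 50.0, "fixed-interactive": 55.0, "control": 0.0}
    cat_effect_v2: dict[str, float] = {
        "fixed": -3.0, "fixed-interactive": -1.5, "control": 0.0}
    cat_effect_v3: dict[str, float] = {
        "fixed": -3.0, "fixed-interactive": -2.5, "control": 0.0}
    sixmwt_outcome_sd: float = 30.0
    cat_outcome_sd: float = 3.0

    @model_validator(mode="after")
    def _arms_covered(self):
        for d in (self.sixmwt_effect_v2, self.sixmwt_effect_v3,
                  self.cat_effect_v2, self.cat_effect_v3):
            missing = set(ARMS) - set(d)
            if missing:
                raise ValueError(f"treatment effects missing arms: {sorted(missing)}")
        return self


@dataclass
class PatientBaseline:
    """Roster entry plus baseline (V1) outcome for one simulated patient."""

    patient_id: str
    site: str
    age: float
    sex: str
    fev1_pct_pred: float
    outcome: OutcomeRecord  # visit V1


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float = -np.inf, high: float = np.inf) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low < x < high:
            return float(x)
    raise RuntimeError("truncated normal rejection sampling failed")


def draw_patient(
    config: SimCohortConfig,
    rng: np.random.Generator,
    patient_id: str = "P0001",
    site: str | None = None,
) -> tuple[SimPatientParams, PatientBaseline]:
    """Draw one patient's latent parameters and baseline record.

    Baseline 6MWT distance is Normal(356, 98) truncated above 150 m;
    latent capacity is the implied mean test speed jittered by a small
    log-normal factor, so a patient can over- or under-perform their
    baseline test relative to true capacity.
    """
    site = site if site is not None else str(config.sites[0])
    dist = _truncated_normal(rng, config.sixmwt_mean, config.sixmwt_sd,
                             low=config.sixmwt_min)
    capacity = dist / SIXMWT_DURATION_S * float(np.exp(rng.normal(0.0, 0.08)))
    params = SimPatientParams(
        capacity=capacity,
        adherence_prob=float(np.clip(rng.normal(0.85, 0.08), 0.3, 1.0)),
    )
    cat = int(np.clip(round(rng.normal(config.cat_mean, config.cat_sd)), 0, 40))
    mmrc = int(rng.choice(5, p=[0.10, 0.30, 0.35, 0.20, 0.05]))
    fev1 = _truncated_normal(rng, config.fev1_mean, config.fev1_sd,
                             low=20.0, high=79.9)
    age = _truncated_normal(rng, config.age_mean, config.age_sd, low=21.0)
    sex = "M" if rng.random() < config.male_fraction else "F"
    baseline = PatientBaseline(
        patient_id=patient_id,
        site=site,
        age=round(age, 1),
        sex=sex,
        fev1_pct_pred=round(fev1, 2),
        outcome=OutcomeRecord(
            patient_id=patient_id, visit="V1",
            cat=cat, mmrc=mmrc, sixmwt_distance=round(dist, 1),
        ),
    )
    return params, baseline


def simulate_6mwt(
    params: SimPatientParams,
    rng: np.random.Generator,
    distance: float | None = None,
) -> SixMwtResult:
    """Simulate one 6-minute walk test.

    If ``distance`` is given (e.g. the recorded baseline test) the split
    speeds are scaled to reproduce it; otherwise the test reflects current
    capacity with a small maximal-effort reserve above the sustainable
    speed.
    """
    if distance is None:
        mean_speed = (params.capacity * params.sixmwt_performance
                      * float(np.exp(rng.normal(0.0, 0.03))))
    else:
        mean_speed = distance / SIXMWT_DURATION_S
    noise = np.exp(rng.normal(0.0, 0.01, size=6))
    splits = mean_speed * _SIXMWT_PROFILE * noise
    return SixMwtResult.from_splits(splits)


def simulate_session(
    params: SimPatientParams,
    prescribed_speed: float,
    duration: float,
    rng: np.random.Generator,
    patient_id: str = "P0001",
    session_date: _dt.date = _dt.date(2017, 5, 1),
) -> WalkSession:
    """Simulate one walking session at a prescribed speed and duration.

    The achieved speed is the prescription capped at the patient's noisy
    capacity; Borg and the SpO2 trace follow the linear intensity-response
    models described in the module docstring.
    """
    if prescribed_speed <= 0:
        raise ValueError("prescribed speed must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    intensity = prescribed_speed / params.capacity
    achieved = min(
        prescribed_speed,
        params.capacity * (1.0 + rng.normal(0.0, params.speed_noise_sd)),
    )
    achieved = max(achieved, 0.05)
    distance = achieved * duration

    raw_borg = params.borg_gain * intensity + rng.normal(0.0, params.borg_noise_sd)
    borg = float(np.clip(np.round(raw_borg * 2) / 2, 0.0, 10.0))

    times = np.arange(SAMPLE_INTERVAL_S, duration + 1e-9, SAMPLE_INTERVAL_S)
    spo2 = np.clip(
        params.baseline_spo2
        - params.desat_propensity * intensity
        + rng.normal(0.0, params.spo2_noise_sd, size=times.size),
        70.0, 100.0,
    )
    hr = np.maximum(
        params.hr_rest + params.hr_gain * intensity
        + rng.normal(0.0, 3.0, size=times.size),
        30.0,
    )
    samples = tuple(zip(times.tolist(), np.round(spo2, 1).tolist(),
                        np.round(hr, 1).tolist()))
    return WalkSession(
        patient_id=patient_id,
        session_date=session_date,
        distance=round(distance, 1),
        duration=float(duration),
        borg=borg,
        samples=samples,
    )


@dataclass
class Trajectory:
    """Everything one simulated patient produces over the trial."""

    patient_id: str
    arm: Arm
    sessions: list[WalkSession]
    final_state: Optional[RegimenState]
    outcomes: list[OutcomeRecord]
    dropout_week: Optional[int]
    final_capacity: float


def simulate_trajectory(
    params: SimPatientParams,
    arm: Arm,
    baseline: OutcomeRecord,
    rng: np.random.Generator,
    weeks: int = 12,
    config: SimCohortConfig | None = None,
    fixed_table: FixedLevelTable | None = None,
    interactive_table: InteractiveLevelTable | None = None,
    start_date: _dt.date = _dt.date(2017, 5, 1),
) -> Trajectory:
    """Play one patient through the trial schedule.

    Days loop over ``weeks`` x 7; each day the patient exercises with
    probability ``adherence_prob``; dropout is drawn once per week and
    truncates the log.  On the fixed regimen the patient walks toward the
    current distance target at a self-selected pace; on the interactive
    regimen a 6MWT initialises the speed prescription (the recorded
    baseline test at enrolment, a fresh simulated test at the
    fixed-to-interactive switch and at top-level re-tests).  V2/V3
    outcomes apply the configured arm effects additively to baseline.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    config = config or SimCohortConfig(weeks=weeks)
    fixed_table = fixed_table or FixedLevelTable()
    interactive_table = interactive_table or InteractiveLevelTable()

    capacity = params.capacity
    state: Optional[RegimenState] = None
    active: Optional[str] = None
    sessions: list[WalkSession] = []
    dropout_week: Optional[int] = None

    def current_params() -> SimPatientParams:
        return params.model_copy(update={"capacity": capacity})

    for week in range(1, weeks + 1):
        if rng.random() < params.dropout_hazard:
            dropout_week = week
            break
        regimen_now = rg.schedule_arm(arm, week, total_weeks=weeks)
        if regimen_now != active:
            if regimen_now == "fixed":
                state = rg.init_fixed(fixed_table)
            elif regimen_now == "interactive":
                mwt = simulate_6mwt(
                    current_params(), rng,
                    distance=baseline.sixmwt_distance if week == 1 else None,
                )
                state = rg.init_interactive(mwt, interactive_table)
            active = regimen_now

        for dow in range(7):
            day = start_date + _dt.timedelta(days=(week - 1) * 7 + dow)
            if active is None or rng.random() >= params.adherence_prob:
                continue
            if active == "fixed":
                target = rg.fixed_target(state, fixed_table)
                pace = capacity  # self-selected, capped at capacity inside
                duration = min(1.05 * target / pace, 3600.0)
                sess = simulate_session(current_params(), pace, duration, rng,
                                        baseline.patient_id, day)
                state = rg.update_fixed(state, [sess], fixed_table)
            else:
                if state.retest_pending:
                    mwt = simulate_6mwt(current_params(), rng)
                    state = rg.apply_retest(state, mwt, interactive_table)
                speed = rg.prescribed_speed(state, interactive_table)
                duration = interactive_table.session_duration_min * 60.0
                sess = simulate_session(current_params(), speed, duration, rng,
                                        baseline.patient_id, day)
                state = rg.update_interactive(state, sess.borg,
                                              interactive_table, date=day)
            sessions.append(sess)
            capacity *= 1.0 + params.training_rate

    outcomes = [baseline]
    for visit, at_week, mwt_eff, cat_eff in (
        ("V2", 6, config.sixmwt_effect_v2, config.cat_effect_v2),
        ("V3", 12, config.sixmwt_effect_v3, config.cat_effect_v3),
    ):
        if at_week > weeks or (dropout_week is not None and dropout_week <= at_week):
            continue
        dist = max(
            0.0,
            baseline.sixmwt_distance + mwt_eff[arm]
            + rng.normal(0.0, config.sixmwt_outcome_sd),
        )
        cat = int(np.clip(
            round(baseline.cat + cat_eff[arm]
                  + rng.normal(0.0, config.cat_outcome_sd)),
            0, 40,
        ))
        outcomes.append(OutcomeRecord(
            patient_id=baseline.patient_id, visit=visit,
            cat=cat, mmrc=baseline.mmrc, sixmwt_distance=round(dist, 1),
        ))
    return Trajectory(
        patient_id=baseline.patient_id,
        arm=arm,
        sessions=sessions,
        final_state=state,
        outcomes=outcomes,
        dropout_week=dropout_week,
        final_capacity=capacity,
    )


@dataclass
class CohortData:
    """Full simulated trial: roster, session log, and visit outcomes."""

    roster: pd.DataFrame
    sessions: list[WalkSession]
    outcomes: pd.DataFrame
    trajectories: list[Trajectory] = field(default_factory=list)


def simulate_cohort(config: SimCohortConfig | None = None) -> CohortData:
    """Simulate a complete three-arm cohort under ``config``.

    Arms are assigned in a balanced rotation across the roster (exactly
    ``n_per_arm`` per arm) with sites cycled; all randomness flows through
    one generator seeded by ``config.seed``, so a fixed seed reproduces the
    cohort byte for byte.
    """
    config = config or SimCohortConfig()
    rng = np.random.default_rng(config.seed)
    rows, out_rows, all_sessions, trajectories = [], [], [], []
    n_total = config.n_per_arm * len(ARMS)
    for i in range(n_total):
        pid = f"P{i + 1:04d}"
        site = str(config.sites[i % len(config.sites)])
        arm = ARMS[i % len(ARMS)]
        params, base = draw_patient(config, rng, patient_id=pid, site=site)
        traj = simulate_trajectory(
            params, arm, base.outcome, rng,
            weeks=config.weeks, config=config, start_date=config.start_date,
        )
        rows.append({
            "patient_id": pid, "site": site, "arm": arm,
            "age": base.age, "sex": base.sex,
            "fev1_pct_pred": base.fev1_pct_pred,
            "cat": base.outcome.cat, "mmrc": base.outcome.mmrc,
            "sixmwt_distance": base.outcome.sixmwt_distance,
            "dropout_week": traj.dropout_week,
        })
        for rec in traj.outcomes:
            out_rows.append({
                "patient_id": rec.patient_id, "visit": rec.visit,
                "cat": rec.cat, "mmrc": rec.mmrc,
                "sixmwt_distance": rec.sixmwt_distance,
            })
        all_sessions.extend(traj.sessions)
        trajectories.append(traj)
    return CohortData(
        roster=pd.DataFrame(rows),
        sessions=all_sessions,
        outcomes=pd.DataFrame(out_rows),
        trajectories=trajectories,
    )
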