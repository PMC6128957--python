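# Methods

## Regimen engines

Both walking regimens are pure state machines: an update takes a state and
an input (one day's sessions, or one post-session Borg score) and returns a
new state carrying an append-only event history. Replaying the same inputs
from the same initial state therefore reproduces the final state and the
history exactly, which is what makes the monitoring reports and the test
oracles possible.

**Fixed regimen.** Six daily distance targets (600, 1200, 1800, 2400,
3000, 3600 m) and an achievement counter. A calendar day qualifies when the
*sum* of that day's session distances reaches the current target; a day is
credited at most once, and the 14 qualifying days needed for a level-up do
not have to be consecutive. We read the daily requirement as accumulated
distance rather than a single continuous walk because the platform's
telemetry is per-session and patients commonly split a prescription into
bouts; aggregation is the weaker (more permissive) reading and the one the
data model supports losslessly. At the top level, completed achievement
cycles are logged (`level_cap`) and the counter resets, so the invariant
`0 <= achievements < 14` holds everywhere.

**Interactive regimen.** Twelve speed levels over a base speed of 80 % of
the 6MWT maximum walking speed. Level definitions are configurable; the
defaults scale the base speed by 1.00, 1.02, …, 1.22 across the twelve
levels with a fixed 30-minute session. We chose speed as the quantity the
levels modulate (duration fixed) because the prescription is delivered as
a metronome cadence, which paces speed, not duration; the ~2 % per-level
increments keep the whole ladder inside a plausible fraction of capacity
(0.80–0.98 of v_max). Borg feedback: `<= 3` for three consecutive sessions
moves the level up, `>= 7` for three consecutive sessions moves it down,
any intermediate score clears both streaks, and every level change clears
both streaks. The down-rule duration is not independently specified
anywhere we could find, so it is symmetric with the up-rule (three
sessions) and configurable via `streak_length`. Reaching level 12 freezes
the engine until a repeat 6MWT is applied, which recomputes the base speed
and restarts at level 7.

**Borg grid.** Modified Borg ratings live on the half-point grid
{0, 0.5, …, 10}; thresholds are compared with `<=` / `>=` exactly.

**Metronome cadence.** `cadence = speed / stride_length * 60` steps/min
with a default stride of 0.70 m — a typical value for older adults walking
at ~1 m/s. Stride length is a per-patient setting in practice; the default
only anchors the unit conversion.

**SpO2 alerting.** An alert fires at the first sample strictly below 90 %.
While saturation stays continuously below threshold, repeat alerts are
suppressed for a 30 s debounce window (a phone vibrating every second
would be ignored); recovery to >= 90 % re-arms the alert immediately so a
new dip always alerts. Threshold and debounce are parameters.

**Arm schedule.** `fixed` walks the fixed regimen for all 12 weeks;
`fixed-interactive` switches to the interactive regimen at week 7 (a fresh
6MWT initialises it); `control` has no prescription.

## 6MWT computation

The walking-speed trace is treated as piecewise linear between samples.
Minute boundaries are inserted as interpolation knots, each of the six
split speeds is the exact trapezoidal integral of the trace over its
minute divided by 60 s, total distance is the integral over [0, 360] s,
and the maximum walking speed is the largest split. Time-weighted
averaging makes the splits robust to uneven sampling; a trace that does
not cover the full six minutes is rejected rather than extrapolated.

## Eligibility

Strict inequalities as specified for the screening criteria: age > 20
years, post-bronchodilator FEV1 < 80 % predicted, 6MWT distance > 150 m.
Eligibility is monotone in walking distance by construction.

## Synthetic cohort

The simulator generates exactly the behavioural surface the other modules
read, under study conditions fixed once:

| parameter | default | meaning |
|---|---|---|
| baseline 6MWT | Normal(356, 98) m, truncated > 150 | enrolment capacity distribution |
| CAT | Normal(15.6, 7.8), clipped 0–40 | baseline symptom burden |
| FEV1 %pred | Normal(58.6, 15.7), truncated (20, 80) | disease severity within eligibility |
| age | Normal(64, 8), truncated > 21; 82 % male | demographics |
| capacity | baseline mean test speed × LogNormal(0, 0.08) | sustainable walking speed, m/s |
| `sixmwt_performance` | 1.05 | mean 6MWT speed relative to capacity (the test is near-maximal) |
| `borg_gain` | 5 Borg units per unit relative intensity | Borg ≈ 5 at prescription = capacity |
| `borg_noise_sd` | 1.0 | session-to-session perception noise |
| `desat_propensity` | 4 %-points per unit intensity, from SpO2 96 | exercise desaturation |
| `adherence_prob` | ~Normal(0.85, 0.08) per day | probability of exercising |
| `dropout_hazard` | 0.02 per week | attrition |
| `training_rate` | 0.002 per completed session | ≈ +15 % capacity over 12 weeks |

A session at prescribed speed v against capacity c has relative intensity
x = v/c; achieved speed is min(v, c·(1+ε)); Borg is
clip(round2(5x + noise)) on the half-point grid; SpO2 samples every 30 s
are baseline − 4x + noise clipped to [70, 100]. The linear Borg response
is the simplest monotone model that can reach both Borg thresholds, and
with the default gain the closed loop is stable: the prescription ladder
(0.80–0.98 of measured v_max) maps to Borg ≈ 4–5, inside the (3, 7) band,
while a patient whose capacity outgrows (or was underestimated by) the
last 6MWT reports low Borg and climbs.

Visit outcomes are baseline plus an additive arm effect plus noise at V2
(6 weeks) and V3 (12 weeks): 6MWT +25 m at V2 and +50/+55 m at V3 in the
intervention arms (the design's detectable difference), CAT −3 at V2 in
the fixed arm and −1.5/−2.5 in the fixed-interactive arm, zero in control;
residual SDs 30 m and 3 points. These defaults make the fixed arm show a
CAT improvement at 6 weeks, matching the direction of effect such trials
target; magnitudes are illustrative, not estimates.

What the simulator does **not** model: heart-rate dynamics beyond noise
around a linear intensity response, weather/season effects on adherence,
exacerbations, learning effects on the 6MWT, or any correlation structure
between CAT and walking outcomes. Tests passing on this cohort therefore
demonstrate that the *logic* is correct under the stated response models,
not that the platform improves real patients.

## Trial statistics

* **Sample size**: n0 = 2((z_{1−α/2} + z_{power})·σ/δ)² per group, inflated
  by 1/(1−dropout), then rounded to the *nearest* integer — with the
  default design (δ=50, σ=60, α=0.05, power 0.80, dropout 0.20) this gives
  28 per group / 84 total; the ceiling convention (29) is available via
  `rounding="ceil"`. Rounding after inflation is what reproduces the
  28-per-group design.
* **Power**: Monte-Carlo rejection fraction of the two-sided two-sample
  t-test over vectorised simulated trials, cross-checkable against the
  noncentral-t closed form (`analytic_power`). At the unadjusted n = 23
  the exact power is 0.789; the normal-approximation formula slightly
  understates the n a t-test needs, which is why the Monte-Carlo estimate
  sits just below 80 %.
* **Randomization**: permuted blocks of size 3 (one slot per arm) within
  site × stratum cells; strata dichotomise FEV1 %predicted at 50 (the
  conventional moderate/severe boundary) and CAT at 10 (the low/medium
  impact boundary); both cut-points configurable. Within any cell, arm
  counts can never differ by more than one.
* **Baseline ANOVA**: explicit between/within sums of squares. We wrote
  the sums of squares out rather than delegating so that identical groups
  return F = 0, p = 1 (the library routine returns NaN there); random-data
  agreement with `scipy.stats.f_oneway` to 1e-10 relative error is part of
  the test suite.
* **Repeated measures**: mixed between–within ANOVA (between: arm, within:
  visit) on complete cases only, no sphericity correction — the smallest
  faithful implementation of a repeated-measures comparison of V1/V2/V3;
  the model fit is delegated to `pingouin.mixed_anova`. Because the
  within-group/between-group ambiguity matters for a 6-week CAT
  comparison, `rm_anova` reports both: per-arm paired t-tests on the
  change scores (V2−V1, V3−V1) *and* a between-arm one-way ANOVA on each
  change score, alongside the interaction F.

## Numerical and interface conventions

* All randomness flows through `numpy.random.Generator`; every simulation
  entry point takes a seed or generator, and identical seeds give
  byte-identical outputs (session logs serialise floats with `repr`).
* Dates are ISO-8601 calendar dates; the day boundary is the date attached
  to the session record, with no timezone arithmetic.
* CSV is UTF-8, comma-separated, header required. JSONL session logs embed
  the vitals stream; CSV logs keep it in a `<stem>.samples.jsonl`
  companion keyed by session id.
* Malformed session rows are collected with line numbers and reported;
  a read fails outright only when no row is valid. Config files reject
  unknown keys.
* `run-regimen` needs a 6MWT maximum speed to initialise the interactive
  phase, which a bare session log does not carry: it uses the
  `sixmwt_max_speed` config key when present and otherwise falls back to
  the fastest mean session speed observed before the switch.

## Problem sizes used in the test suite

The default synthetic trial is 28 patients per arm for 12 weeks (~3,800
sessions), the size the design formula prescribes. Distributional checks
use 1,000 draws (baseline calibration, Borg-gain recovery) or 10,000
replicates (Monte-Carlo power, engine-vs-oracle replay); the null
calibration of the repeated-measures interaction uses 1,000 simulated
trials of 8 patients per arm. These sizes give Monte-Carlo error
comfortably inside the asserted tolerances.

## Known limitations

* The interactive level ladder (speed fractions, fixed 30-minute
  duration) is a design choice, not a published table; deployments should
  override it via configuration.
* Compliance is day-based (a day with any session counts); session-count
  or minutes-based compliance would need only a different aggregation but
  is not implemented.
* The repeated-measures ANOVA drops incomplete cases rather than fitting
  a mixed-effects model; with the attrition a real trial sees, a
  likelihood-based longitudinal model would use the data better.
* `site_view` filters rows; it is an analytics convenience, not an access
  control mechanism.
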