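# pulmorehab

Home-based pulmonary rehabilitation (PR) improves exercise capacity and
quality of life in chronic obstructive pulmonary disease (COPD), but only
if the daily walking prescription adapts to the patient and someone is
watching the telemetry.  `pulmorehab` implements the complete decision
logic of a mobile PR platform as a tested Python library plus CLI, for
people building or evaluating tele-rehabilitation programmes:

* **Regimen engines** (`pulmorehab.regimen`) — two replayable state
  machines.  The *fixed* regimen walks six daily distance targets
  (600–3600 m); a day whose accumulated distance reaches the target is an
  achievement, and 14 achievements advance the level.  The *interactive*
  regimen prescribes walking speed over 12 levels, initialised at 80 % of
  the maximum walking speed v<sub>max</sub> from a 6-minute walk test
  (6MWT): level *k* prescribes 0.80·v<sub>max</sub>·f<sub>k</sub> with
  f<sub>k</sub> = 1.00, 1.02, …, 1.22, paced by a metronome.  Three
  consecutive sessions with modified Borg score ≤ 3 raise the level, three
  with Borg ≥ 7 lower it; reaching level 12 triggers a repeat 6MWT and a
  reset to level 7.  In-session pulse-oximetry alerting fires when SpO₂
  drops below 90 % (debounced, re-armed on recovery).
* **Assessment** (`pulmorehab.assessment`) — 6MWT split speeds, distance
  and v<sub>max</sub> from a speed trace; trial eligibility (age > 20,
  FEV₁ < 80 % predicted, 6MWT > 150 m); CAT/mMRC/6MWT visit records and
  Likert patient-global-assessment summaries.
* **Monitoring** (`pulmorehab.monitoring`) — day-based compliance against
  a prescription calendar, flag lists (any SpO₂ < 90 % or Borg ≥ 7),
  site-scoped record access, per-patient PR reports.
* **Trial statistics** (`pulmorehab.trial_stats`) — two-sample sample size
  n = 2((z₁₋α/₂+z₁₋β)·σ/δ)² with dropout inflation, Monte-Carlo and
  noncentral-t power, stratified permuted-block 1:1:1 randomization
  (FEV₁ × CAT strata within site), one-way baseline ANOVA, and mixed
  between–within (repeated-measures) ANOVA of V1/V2/V3 outcomes with
  per-arm change scores.
* **Synthetic cohort** (`pulmorehab.cohort`) — a seeded simulator of COPD
  patients (latent walking capacity, linear Borg-vs-intensity response,
  desaturation, adherence and dropout) that exercises every branch above
  without any external data.

## Worked example

```python
from pulmorehab import regimen as rg
from pulmorehab.assessment import compute_6mwt
from pulmorehab.trial_stats import sample_size, empirical_power

# 6MWT from a walking-speed trace: 1.40 m/s for the first minute,
# 1.25 m/s afterwards.
res = compute_6mwt([(0.0, 1.40), (60.0, 1.40), (60.01, 1.25), (360.0, 1.25)])
print(round(res.distance, 1), round(res.max_speed, 3))   # 459.0 1.4

# Interactive regimen: base speed = 80% of vmax, level 1, metronome pace.
state = rg.init_interactive(res)
speed = rg.prescribed_speed(state, rg.InteractiveLevelTable())
print(state.base_speed, speed, rg.metronome_cadence(speed))  # 1.12 1.12 96.0

# Three sessions at Borg <= 3 raise the level.
for borg in (2, 2.5, 3):
    state = rg.update_interactive(state, borg)
print(state.level)                                       # 2

# Trial design: 28 per group (84 total) from delta=50 m, sd=60 m,
# alpha=.05, power=80%, dropout=20%; Monte-Carlo power at the
# unadjusted n=23 is ~0.79-0.80.
ss = sample_size()
print(ss.n_per_group, ss.n_total)                        # 28 84
print(empirical_power(23, 50, 60, reps=10_000, seed=1))  # 0.7941
```

The base speed 1.12 m/s is 80 % of the measured v<sub>max</sub> = 1.40 m/s;
at the default 0.70 m stride that is a 96 steps/min metronome.  The level
moves to 2 because all three Borg scores were at or below the up-threshold
of 3.

From the shell, the same pieces run as subcommands:

```bash
pulmorehab simulate --seed 1 --out sim/          # roster, sessions, outcomes
pulmorehab run-regimen --arm fixed-interactive \
    --sessions sim/sessions.jsonl --out history.jsonl
pulmorehab monitor --sessions sim/sessions.jsonl \
    --roster sim/roster.csv --site site-1 --out mon/
pulmorehab power                                  # {"n_per_group": 28, ...}
pulmorehab analyze --outcomes sim/outcomes.csv \
    --assignments sim/roster.csv --out analysis.json
```

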