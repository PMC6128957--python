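"""Fixed and interactive walking-regimen engines, alerting, scheduling."""

import datetime as dt
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pulmorehab.regimen as rg
from pulmorehab.assessment import SixMwtResult
from pulmorehab.regimen import (
    FixedLevelTable,
    InteractiveLevelTable,
    WalkSession,
    apply_retest,
    fixed_target,
    init_fixed,
    init_interactive,
    metronome_cadence,
    monitor_spo2,
    prescribed_speed,
    schedule_arm,
    update_fixed,
    update_interactive,
)

from conftest import make_session

DAY = dt.date(2017, 5, 1)


def mwt(max_speed: float) -> SixMwtResult:
    return SixMwtResult.from_splits([max_speed] * 6)


# ---------------------------------------------------------------------------
# Fixed regimen
# ---------------------------------------------------------------------------

class TestFixedRegimen:
    def test_init_starts_at_600m(self, fixed_table):
        state = init_fixed(fixed_table)
        assert state.level == 1 and state.achievements == 0
        assert fixed_target(state, fixed_table) == 600.0

    def test_single_level_table_caps_advancement(self):
        table = FixedLevelTable(distances=(600.0,))
        state = init_fixed(table)
        for d in range(30):
            day = DAY + dt.timedelta(days=d)
            state = update_fixed(state, [make_session(700.0, day)], table)
        assert state.level == 1

    def test_empty_distance_list_rejected(self):
        with pytest.raises(ValueError):
            FixedLevelTable(distances=())

    def test_nonincreasing_distances_rejected(self):
        with pytest.raises(ValueError):
            FixedLevelTable(distances=(600.0, 600.0, 1800.0))

    def test_fourteenth_achievement_levels_up(self, fixed_table):
        state = init_fixed(fixed_table)
        for d in range(13):
            state = update_fixed(
                state, [make_session(650.0, DAY + dt.timedelta(days=d))],
                fixed_table)
        assert state.level == 1 and state.achievements == 13
        state = update_fixed(
            state, [make_session(650.0, DAY + dt.timedelta(days=13))], fixed_table)
        assert state.level == 2 and state.achievements == 0
        assert fixed_target(state, fixed_table) == 1200.0

    def test_top_level_stays_capped(self, fixed_table):
        state = init_fixed(fixed_table)
        for d in range(14 * 6 + 10):
            state = update_fixed(
                state, [make_session(4000.0, DAY + dt.timedelta(days=d))],
                fixed_table)
        assert state.level == 6
        assert fixed_target(state, fixed_table) == 3600.0

    def test_same_day_sessions_aggregate_to_one_achievement(self, fixed_table):
        state = init_fixed(fixed_table)
        state = update_fixed(
            state, [make_session(300.0, DAY), make_session(320.0, DAY)],
            fixed_table)
        assert state.achievements == 1

    def test_below_target_day_earns_nothing(self, fixed_table):
        state = init_fixed(fixed_table)
        state = update_fixed(state, [make_session(599.0, DAY)], fixed_table)
        assert state.achievements == 0

    def test_sessions_spanning_dates_rejected(self, fixed_table):
        state = init_fixed(fixed_table)
        with pytest.raises(ValueError, match="dates"):
            update_fixed(
                state,
                [make_session(650.0, DAY),
                 make_session(650.0, DAY + dt.timedelta(days=1))],
                fixed_table)

    def test_level_ups_every_14_qualifying_days(self, fixed_table):
        """Exactly 14 qualifying days separate consecutive level-ups."""
        state = init_fixed(fixed_table)
        level_up_days = []
        for d in range(70):
            state = update_fixed(
                state, [make_session(4000.0, DAY + dt.timedelta(days=d))],
                fixed_table)
            if state.history[-1]["event"] == "level_up":
                level_up_days.append(d + 1)
        assert level_up_days == [14, 28, 42, 56, 70]
        assert state.level == 6

    def test_replay_reproduces_state_and_history(self, fixed_table):
        days = [[make_session(650.0 if d % 3 else 500.0,
                              DAY + dt.timedelta(days=d))] for d in range(40)]

        def run():
            s = init_fixed(fixed_table)
            for sessions in days:
                s = update_fixed(s, sessions, fixed_table)
            return s

        assert run() == run()


# ---------------------------------------------------------------------------
# Interactive regimen
# ---------------------------------------------------------------------------

class TestInteractiveRegimen:
    @pytest.mark.parametrize("vmax,base", [(1.5, 1.2), (1.0, 0.8)])
    def test_init_base_speed_is_80_percent_of_max(self, vmax, base,
                                                  interactive_table):
        state = init_interactive(mwt(vmax), interactive_table)
        assert state.level == 1
        assert state.base_speed == pytest.approx(base)
        assert prescribed_speed(state, interactive_table) == pytest.approx(
            base * interactive_table.speed_fractions[0])

    def test_init_rejects_nonpositive_max_speed(self, interactive_table):
        with pytest.raises(ValueError):
            init_interactive(SixMwtResult.model_construct(
                distance=0.0, split_speeds=(0,) * 6, max_speed=0.0),
                interactive_table)

    def test_three_low_borg_sessions_level_up(self, interactive_table):
        state = init_interactive(mwt(1.5), interactive_table)
        for b in (2, 2):
            state = update_interactive(state, b, interactive_table)
            assert state.level == 1
        state = update_interactive(state, 2, interactive_table)
        assert state.level == 2
        assert state.low_borg_streak == 0 and state.high_borg_streak == 0

    def test_intermediate_borg_breaks_streak(self, interactive_table):
        state = init_interactive(mwt(1.5), interactive_table)
        for b in (2, 5, 2):
            state = update_interactive(state, b, interactive_table)
        assert state.level == 1
        assert state.low_borg_streak == 1  # only the final 2 counts

    def test_level_floor_at_one(self, interactive_table):
        state = init_interactive(mwt(1.5), interactive_table)
        for b in (8, 8, 8, 9, 9, 9):
            state = update_interactive(state, b, interactive_table)
        assert state.level == 1

    def test_three_high_borg_sessions_level_down(self, interactive_table):
        state = init_interactive(mwt(1.5), interactive_table)
        for b in (2, 2, 2, 2, 2, 2):  # climb to level 3
            state = update_interactive(state, b, interactive_table)
        assert state.level == 3
        for b in (7, 8, 10):
            state = update_interactive(state, b, interactive_table)
        assert state.level == 2

    def test_top_level_sets_retest_and_blocks_updates(self, interactive_table):
        state = init_interactive(mwt(1.5), interactive_table)
        state = replace(state, level=11)
        for b in (2, 2, 2):
            state = update_interactive(state, b, interactive_table)
        assert state.level == 12 and state.retest_pending
        with pytest.raises(ValueError, match="apply_retest"):
            update_interactive(state, 2, interactive_table)

    def test_retest_resets_to_level_7_with_new_base(self, interactive_table):
        state = init_interactive(mwt(1.5), interactive_table)
        state = replace(state, level=11)
        for b in (2, 2, 2):
            state = update_interactive(state, b, interactive_table)
        new = apply_retest(state, mwt(2.0), interactive_table)
        assert new.level == 7
        assert new.base_speed == pytest.approx(1.6)
        assert not new.retest_pending
        assert new.low_borg_streak == 0 and new.high_borg_streak == 0
        # identical repeat test keeps the base speed
        state2 = apply_retest(state, mwt(1.5), interactive_table)
        assert state2.base_speed == pytest.approx(1.2) and state2.level == 7

    def test_retest_without_pending_rejected(self, interactive_table):
        state = init_interactive(mwt(1.5), interactive_table)
        with pytest.raises(ValueError, match="pending"):
            apply_retest(state, mwt(1.5), interactive_table)

    @pytest.mark.parametrize("bad", [-1, 10.5, 3.25])
    def test_borg_off_grid_rejected(self, bad, interactive_table):
        state = init_interactive(mwt(1.5), interactive_table)
        with pytest.raises(ValueError):
            update_interactive(state, bad, interactive_table)


def replay_oracle(borg_seq, table: InteractiveLevelTable, start_level=1):
    """Independent brute-force replay of the interactive level rules."""
    level, low, high, pending = start_level, 0, 0, False
    consumed = 0
    for b in borg_seq:
        if pending:
            break
        consumed += 1
        if b <= table.borg_up_threshold:
            low, high = low + 1, 0
        elif b >= table.borg_down_threshold:
            low, high = 0, high + 1
        else:
            low = high = 0
        if low == table.streak_length:
            level = min(level + 1, table.n_levels)
            low = high = 0
            if level == table.n_levels:
                pending = True
        elif high == table.streak_length:
            level = max(level - 1, 1)
            low = high = 0
    return level, low, high, pending, consumed


def engine_replay(borg_seq, table: InteractiveLevelTable):
    state = init_interactive(mwt(1.5), table)
    consumed = 0
    for b in borg_seq:
        if state.retest_pending:
            break
        state = update_interactive(state, b, table)
        consumed += 1
    return (state.level, state.low_borg_streak, state.high_borg_streak,
            state.retest_pending, consumed)


class TestInteractiveProperties:
    @given(st.lists(st.sampled_from([x / 2 for x in range(21)]), max_size=30))
    def test_engine_matches_bruteforce_oracle(self, borg_seq):
        table = InteractiveLevelTable()
        assert engine_replay(borg_seq, table) == replay_oracle(borg_seq, table)

    @given(st.lists(st.sampled_from([x / 2 for x in range(21)]), max_size=30),
           st.integers(2, 5), st.integers(1, 4))
    def test_invariants_under_fuzzing(self, borg_seq, n_levels, streak_length):
        table = InteractiveLevelTable(
            n_levels=n_levels,
            speed_fractions=tuple(1.0 + 0.02 * k for k in range(n_levels)),
            reset_level=min(2, n_levels), streak_length=streak_length)
        state = init_interactive(mwt(1.5), table)
        for b in borg_seq:
            if state.retest_pending:
                state = apply_retest(state, mwt(1.5), table)
            prev_level = state.level
            state = update_interactive(state, b, table)
            assert 1 <= state.level <= table.n_levels
            assert state.low_borg_streak < table.streak_length
            assert state.high_borg_streak < table.streak_length
            if state.level != prev_level:
                assert state.low_borg_streak == 0
                assert state.high_borg_streak == 0
            if table.borg_up_threshold < b < table.borg_down_threshold:
                assert state.low_borg_streak == 0
                assert state.high_borg_streak == 0

    @given(st.lists(st.sampled_from([x / 2 for x in range(21)]), max_size=20))
    def test_replay_determinism(self, borg_seq):
        table = InteractiveLevelTable()

        def run():
            s = init_interactive(mwt(1.3), table)
            for b in borg_seq:
                if s.retest_pending:
                    break
                s = update_interactive(s, b, table)
            return s

        assert run() == run()


# ---------------------------------------------------------------------------
# Cadence, alerting, scheduling
# ---------------------------------------------------------------------------

class TestMetronome:
    @pytest.mark.parametrize("speed,stride,cadence",
                             [(1.2, 0.72, 100.0), (0.7, 0.70, 60.0)])
    def test_cadence(self, speed, stride, cadence):
        assert metronome_cadence(speed, stride) == pytest.approx(cadence)

    @pytest.mark.parametrize("speed,stride", [(1.2, 0.0), (0.0, 0.7), (-1, 0.7)])
    def test_nonpositive_inputs_rejected(self, speed, stride):
        with pytest.raises(ValueError):
            metronome_cadence(speed, stride)


def stream(*spo2s, dt_s=10.0, hr=95.0):
    return [(i * dt_s, s, hr) for i, s in enumerate(spo2s, start=1)]


class TestSpo2Monitor:
    def test_alert_on_first_sample_below_90(self):
        alerts = monitor_spo2(stream(95, 92, 89))
        assert len(alerts) == 1
        assert alerts[0].spo2_percent == 89
        assert alerts[0].elapsed_seconds == 30.0

    def test_exactly_90_is_not_an_alert(self):
        assert monitor_spo2(stream(90, 90, 90)) == []

    def test_continuous_run_debounced_to_one_alert(self):
        # three samples within one 30 s debounce window
        assert len(monitor_spo2(stream(89, 88, 87))) == 1

    def test_realert_after_debounce_elapses(self):
        alerts = monitor_spo2(stream(89, 88, 87, 86, 85, dt_s=10.0))
        # below at t=10; next alert allowed at t>=40
        assert [a.elapsed_seconds for a in alerts] == [10.0, 40.0]

    def test_recovery_rearms_immediately(self):
        alerts = monitor_spo2(stream(89, 93, 89))
        assert [a.spo2_percent for a in alerts] == [89, 89]

    def test_unsorted_stream_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            monitor_spo2([(10.0, 95, 90), (5.0, 89, 90)])

    @given(st.lists(st.integers(80, 100), min_size=1, max_size=40))
    def test_alert_soundness_and_completeness(self, spo2s):
        samples = stream(*spo2s)
        alerts = monitor_spo2(samples)
        assert all(a.spo2_percent < 90.0 for a in alerts)
        alert_times = {a.elapsed_seconds for a in alerts}
        # every maximal below-threshold run contains at least one alert
        run_start = None
        for t, s, _ in samples + [(1e9, 100, 90)]:
            if s < 90 and run_start is None:
                run_start = t
            elif s >= 90 and run_start is not None:
                assert any(run_start <= at < t for at in alert_times)
                run_start = None


class TestArmSchedule:
    @pytest.mark.parametrize("arm,week,expected", [
        ("fixed", 1, "fixed"), ("fixed", 12, "fixed"),
        ("fixed-interactive", 6, "fixed"),
        ("fixed-interactive", 7, "interactive"),
        ("fixed-interactive", 12, "interactive"),
        ("control", 1, None), ("control", 12, None),
    ])
    def test_schedule(self, arm, week, expected):
        assert schedule_arm(arm, week) == expected

    @pytest.mark.parametrize("week", [0, 13])
    def test_week_out_of_range(self, week):
        with pytest.raises(ValueError):
            schedule_arm("fixed", week)

    def test_unknown_arm(self):
        with pytest.raises(ValueError):
            schedule_arm("sham", 1)


class TestWalkSessionValidation:
    def test_unsorted_samples_rejected(self):
        with pytest.raises(ValueError):
            make_session(samples=((10.0, 95, 90), (5.0, 94, 91)))

    def test_bad_spo2_rejected(self):
        with pytest.raises(ValueError):
            make_session(samples=((10.0, 101.0, 90),))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            make_session(distance=-5.0)

    def test_mean_speed(self):
        assert make_session(distance=900.0, duration=1800.0).mean_speed == 0.5
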