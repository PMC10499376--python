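"""Task state machines: closed-loop contracts, timing, termination rules."""

import numpy as np
import pytest

import lickwheel as lw
from helpers import ConstantRotator, MuteAgent, replay_reward_counts
from lickwheel.events import EventCode as E
from lickwheel.events import validate_log


class BudgetRotator:
    """Emits one active tick per unbraked step until the budget runs out.

    It keeps ticking during laser stimulation (the wheel is free then), which
    is how a vigorous animal behaves; those ticks are logged but uncounted.
    """

    def __init__(self, budget: int):
        self.budget = budget
        self._left = budget

    def reset(self):
        self._left = self.budget

    def notify_reinforcer(self):
        pass

    def step(self, t, dt, stim):
        if stim.braked or self._left <= 0:
            return False, 0
        self._left -= 1
        return False, 1


class ZoneSeeker:
    """Rotates forward until it first enters the paired zone, then freezes."""

    def __init__(self):
        self.frozen = False

    def reset(self):
        self.frozen = False

    def notify_reinforcer(self):
        pass

    def step(self, t, dt, stim):
        if stim.in_paired_zone:
            self.frozen = True
        return False, 0 if self.frozen else 1


class TestFreeAccess:
    def test_every_lick_triggers_one_pulse_same_ms(self):
        cfg = lw.default_config("free_access", seed=1)
        log = lw.run_free_access(cfg, lw.preset("concentration_tracker"))
        licks = log.times(E.LICK)
        pulses = log.times(E.SOLENOID_OPEN)
        assert len(licks) > 0 and licks == pulses

    def test_mute_agent_full_length_no_pulses(self):
        cfg = lw.default_config("free_access", seed=2)
        log = lw.run_free_access(cfg, MuteAgent())
        assert log.times(E.SOLENOID_OPEN) == []
        assert log.duration_ms == 10 * 60_000


@pytest.fixture(scope="module")
def spout_log():
    cfg = lw.default_config("spout_training", seed=3)
    return lw.run_spout_training(cfg, lw.preset("concentration_tracker"))


class TestSpoutTraining:
    def test_sixty_trials(self, spout_log):
        assert len(spout_log.times(E.TRIAL_START)) == 60

    def test_five_pulses_at_exact_200ms_spacing(self, spout_log):
        from lickwheel.events import iter_trials

        for _, _, _, seg in iter_trials(spout_log):
            pulses = [e.time_ms for e in seg if e.code is E.SOLENOID_OPEN]
            assert len(pulses) == 5
            assert [b - a for a, b in zip(pulses, pulses[1:])] == [200] * 4

    def test_iti_bounds_20_to_40_s(self, spout_log):
        starts = spout_log.times(E.TRIAL_START)
        ends = spout_log.times(E.TRIAL_END)
        itis = [s - e for e, s in zip(ends, starts[1:])]
        assert all(20_000 <= x <= 40_000 for x in itis)

    def test_deliveries_are_non_contingent(self):
        cfg = lw.default_config("spout_training", seed=4)
        log = lw.run_spout_training(cfg, MuteAgent())
        assert len(log.times(E.TRIAL_START)) == 60
        assert len(log.times(E.SOLENOID_OPEN)) == 300
        assert log.times(E.LICK) == []


class TestOperantFixedRatio:
    def test_constant_rotator_matches_hand_simulation(self):
        """At one constant rate, reward count follows the dead-time recursion:
        first completion after (ratio-1) steps, then one reward per
        access_ms + (ratio-1)*dt of wheel-free time."""
        cfg = lw.default_config("operant_fr", seed=5)
        log = lw.run_operant_fr(cfg, ConstantRotator(1))
        ratio = round(cfg.fixed_ratio_turns * cfg.ticks_per_rotation)
        t_first = (ratio - 1) * cfg.dt_ms
        cycle = cfg.access_ms + (ratio - 1) * cfg.dt_ms
        expected = (cfg.duration_ms - 1 - t_first) // cycle + 1
        assert int(log.metadata["n_reinforcers"]) == expected
        assert len(log.times(E.SOLENOID_OPEN)) == 5 * expected

    def test_immobile_agent_earns_nothing(self):
        cfg = lw.default_config("operant_fr", seed=6)
        log = lw.run_operant_fr(cfg, MuteAgent())
        assert int(log.metadata["n_reinforcers"]) == 0
        assert log.times(E.BRAKE_ON) == []

    def test_inactive_only_rotation_brakes_without_reward(self):
        cfg = lw.default_config("operant_fr", seed=7)
        log = lw.run_operant_fr(cfg, ConstantRotator(-1))
        assert len(log.times(E.BRAKE_ON)) > 0
        assert log.times(E.SOLENOID_OPEN) == []
        assert log.times(E.SPOUT_EXTEND_CMD) == []

    def test_inactive_brake_length_equals_reward_brake_envelope(self):
        cfg = lw.default_config("operant_fr", seed=8)
        log = lw.run_operant_fr(cfg, ConstantRotator(-1))
        ons = log.times(E.BRAKE_ON)
        offs = log.times(E.BRAKE_OFF)
        spans = {off - on for on, off in zip(ons, offs)}
        assert spans == {cfg.brake_lead_ms + cfg.access_ms}

    def test_reward_accounting_matches_replay_oracle(self):
        cfg = lw.default_config("operant_fr", seed=9)
        log = lw.run_operant_fr(cfg, lw.preset("learner"))
        ratio = round(cfg.fixed_ratio_turns * cfg.ticks_per_rotation)
        rewards, timeouts = replay_reward_counts(log, ratio)
        assert rewards == int(log.metadata["n_reinforcers"])
        assert len(log.times(E.BRAKE_ON)) == rewards + timeouts


class TestProgressiveRatio:
    def test_non_responder_ends_at_exactly_15_min(self):
        cfg = lw.default_config("operant_pr", seed=10)
        log, summary = lw.run_operant_pr(cfg, lw.preset("non_responder"))
        assert summary.session_end_ms == 15 * 60_000
        assert summary.n_reinforcers == 0 and summary.breakpoint == 0.0

    def test_three_semilog_ratios_give_breakpoint_081(self):
        # 16 + 32 + 52 active ticks complete costs 0.25, 0.5, 0.81
        cfg = lw.default_config("operant_pr", seed=11)
        log, summary = lw.run_operant_pr(cfg, BudgetRotator(16 + 32 + 52))
        assert summary.n_reinforcers == 3
        assert summary.breakpoint == 0.81
        # and the session ends 15 min after the last reinforcer
        last_pulse_trial_end = summary.session_end_ms
        assert last_pulse_trial_end < 60 * 60_000

    def test_tireless_agent_capped_at_one_hour(self):
        cfg = lw.default_config("operant_pr", seed=12)
        log, summary = lw.run_operant_pr(cfg, ConstantRotator(1))
        assert summary.session_end_ms == 60 * 60_000
        assert log.events[-1].time_ms == 60 * 60_000


class TestOptoPositive:
    def test_burst_during_stimulation_earns_single_stimulation(self):
        cfg = lw.default_config("opto_positive", seed=13)
        ratio = round(cfg.fixed_ratio_turns * cfg.ticks_per_rotation)
        log = lw.run_opto_positive(cfg, BudgetRotator(2 * ratio))
        assert int(log.metadata["n_stimulations"]) == 1
        assert len(log.times(E.ROTATION_TICK)) == 2 * ratio

    def test_immobile_agent_no_laser(self):
        cfg = lw.default_config("opto_positive", seed=14)
        log = lw.run_opto_positive(cfg, MuteAgent())
        assert log.times(E.LASER_ON) == []

    def test_steady_rotator_matches_closed_form(self):
        cfg = lw.default_config("opto_positive", seed=15)
        log = lw.run_opto_positive(cfg, ConstantRotator(1))
        ratio = round(cfg.fixed_ratio_turns * cfg.ticks_per_rotation)
        t_first = (ratio - 1) * cfg.dt_ms
        cycle = cfg.stim_ms + (ratio - 1) * cfg.dt_ms
        expected = (cfg.duration_ms - 1 - t_first) // cycle + 1
        assert int(log.metadata["n_stimulations"]) == expected

    def test_stimulation_spans_exactly_1s(self):
        cfg = lw.default_config("opto_positive", seed=16)
        log = lw.run_opto_positive(cfg, ConstantRotator(1))
        ons = log.times(E.LASER_ON)
        offs = log.times(E.LASER_OFF)
        assert {off - on for on, off in zip(ons, offs)} == {1000}


class TestOptoNegative:
    def test_non_responder_laser_on_throughout(self):
        cfg = lw.default_config("opto_negative", seed=17)
        log = lw.run_opto_negative(cfg, MuteAgent())
        assert log.times(E.LASER_ON) == [0]
        assert log.times(E.LASER_OFF) == []

    def test_every_pause_spans_exactly_3s(self):
        cfg = lw.default_config("opto_negative", seed=18)
        log = lw.run_opto_negative(cfg, lw.preset("learner"))
        offs = log.times(E.LASER_OFF)
        ons = log.times(E.LASER_ON)
        gaps = {on - off for off, on in zip(offs, ons[1:])}
        assert gaps == {3000}

    def test_steady_rotator_matches_closed_form(self):
        cfg = lw.default_config("opto_negative", seed=19)
        log = lw.run_opto_negative(cfg, ConstantRotator(1))
        ratio = round(cfg.fixed_ratio_turns * cfg.ticks_per_rotation)
        t_first = (ratio - 1) * cfg.dt_ms
        cycle = cfg.pause_ms + (ratio - 1) * cfg.dt_ms
        expected = (cfg.duration_ms - 1 - t_first) // cycle + 1
        assert int(log.metadata["n_pauses"]) == expected


class TestWtp:
    def test_immobile_agent_zero_paired_time(self):
        cfg = lw.default_config("wtp", seed=20)
        log, summary = lw.run_wtp(cfg, MuteAgent())
        assert summary.paired_s == 0.0
        assert summary.unpaired_s == 1200.0

    def test_clamped_agent_spends_whole_session_in_paired_zone(self):
        cfg = lw.default_config("wtp", seed=21)
        log, summary = lw.run_wtp(cfg, ZoneSeeker())
        # one tick moves the start position into the paired zone at t=0
        assert summary.paired_s == pytest.approx(1200.0, abs=0.05)

    def test_dwell_conservation(self):
        cfg = lw.default_config("wtp", seed=22)
        log, summary = lw.run_wtp(cfg, lw.preset("indifferent"))
        assert summary.paired_s + summary.unpaired_s == pytest.approx(1200.0, abs=1e-6)

    def test_paired_zone_cues_track_zone(self):
        cfg = lw.default_config("wtp", seed=23)
        log, _ = lw.run_wtp(cfg, lw.preset("indifferent"))
        # entering the paired zone always switches the tone and starts the laser
        for i, e in enumerate(log.events):
            if e.code is E.ZONE_ENTER and e.value == 1:
                trailing = [x.code for x in log.events[i + 1 : i + 4]]
                assert E.LASER_ON in trailing and E.TONE_ON in trailing


class TestMultispout:
    def test_hundred_trials_and_iti_bounds(self, multispout_log):
        starts = multispout_log.times(E.TRIAL_START)
        ends = multispout_log.times(E.TRIAL_END)
        assert len(starts) == 100
        itis = [s - e for e, s in zip(ends, starts[1:])]
        assert all(5000 <= x <= 10000 for x in itis)

    def test_no_delivery_while_spout_retracted(self, multispout_log):
        available = False
        for e in multispout_log.events:
            if e.code is E.SPOUT_EXTEND_CMD:
                available = True
            elif e.code is E.SPOUT_RETRACT_CMD:
                available = False
            elif e.code in (E.SOLENOID_OPEN, E.LICK):
                assert available

    def test_plan_config_mismatch_rejected(self):
        cfg = lw.default_config("multispout", seed=24)
        plans = lw.make_trial_plans(n_trials=50, block_size=10, rng_seed=0)
        with pytest.raises(ValueError, match="plan has 50"):
            lw.run_multispout(cfg, MuteAgent(), plans)

    def test_bit_exact_reproducibility(self):
        cfg = lw.default_config("multispout", seed=25)
        a = lw.run_session(cfg, lw.preset("concentration_tracker"))
        b = lw.run_session(cfg, lw.preset("concentration_tracker"))
        assert a == b


class TestAllTasksEmitValidLogs:
    @pytest.mark.parametrize("task", [
        "free_access", "spout_training", "operant_fr", "operant_pr",
        "opto_positive", "opto_negative", "wtp", "multispout",
    ])
    def test_log_passes_validation(self, task):
        over = {"n_trials": 10} if task in ("spout_training", "multispout") else {}
        if task == "operant_pr":
            over["duration_ms"] = 10 * 60_000
            over["pr_timeout_ms"] = 5 * 60_000
        cfg = lw.default_config(task, seed=26, **over)
        result = lw.run_session(cfg, lw.preset("learner"))
        log = result[0] if isinstance(result, tuple) else result
        assert validate_log(log) == []
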