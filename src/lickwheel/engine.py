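"""Discrete-event behavioral engine.

A millisecond clock drives one state machine per task.  Each run function
consumes agent actions step by step, actuates the virtual spout, brake,
solenoid, tone and laser, and emits a validated :class:`~lickwheel.events.SessionLog`.
Sessions are bit-reproducible: the same (config, agent parameters, seed)
always yields an identical log.

Task repertoire
---------------
free_access
    Closed loop: every lick immediately triggers one solution pulse.
spout_training
    Non-contingent trials: tone + five pulses at a 200 ms inter-pulse
    interval during each 5 s access period.
operant_fr / operant_pr
    Wheel rotation in the active direction earns sucrose under a fixed or
    progressive ratio; rotation in the inactive direction earns an
    equal-length brake engagement with no reward.
opto_positive / opto_negative
    Active rotation earns 1 s of laser stimulation, or pauses continuous
    stimulation for 3 s; responses during the stimulation/pause window are
    logged but do not count toward the next one.
wtp
    Wheel place preference: the wheel circumference is split into two
    half-rotation zones, one paired with continuous laser stimulation; each
    zone is cued by its own tone.
multispout
    Brief-access consumption: 100 trials of 3 s access to one of five
    solutions on a radial spout head, licks triggering delivery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .agent import AgentParams, Stimuli, VirtualMouse
from .config import SessionConfig, config_digest
from .events import SCHEMA_VERSION, Event, EventCode, SessionLog
from .scheduler import TrialPlan, ratio_schedule, sample_iti

__all__ = [
    "run_session",
    "run_free_access",
    "run_spout_training",
    "run_operant_fr",
    "run_operant_pr",
    "run_opto_positive",
    "run_opto_negative",
    "run_wtp",
    "run_multispout",
    "OperantSummary",
    "WtpSummary",
]

E = EventCode


@dataclass
class OperantSummary:
    n_reinforcers: int = 0
    breakpoint: float = 0.0  # cost (wheel turns) of last completed ratio
    n_active_ticks: int = 0
    n_inactive_ticks: int = 0
    n_timeouts: int = 0  # inactive-ratio brake engagements
    session_end_ms: int = 0


@dataclass
class WtpSummary:
    paired_s: float = 0.0
    unpaired_s: float = 0.0
    n_zone_entries: int = 0


def _make_mouse(agent, cfg: SessionConfig) -> VirtualMouse:
    if isinstance(agent, AgentParams):
        # derive the agent stream from the session seed so one seed fixes
        # the whole session
        child = np.random.SeedSequence([cfg.seed, 7]).generate_state(1)[0]
        return VirtualMouse(agent, seed=int(child) & 0x7FFFFFFF)
    return agent  # duck-typed: anything with .step / .notify_reinforcer / .reset


class _Session:
    """Shared clock, event buffer and actuator bookkeeping for one run."""

    def __init__(self, cfg: SessionConfig, agent, rng: np.random.Generator | None = None):
        self.cfg = cfg
        self.mouse = _make_mouse(agent, cfg)
        if hasattr(self.mouse, "reset"):
            self.mouse.reset()
        self.rng = rng if rng is not None else np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 11]).generate_state(1)[0]
        )
        self.t = 0
        self.events: list[Event] = []
        self.stim = Stimuli()
        self.stim.solution = cfg.solution_index
        self.emit(E.SESSION_START)

    def emit(self, code: EventCode, value: int = 0) -> None:
        self.events.append(Event(self.t, code, value))

    def run_until(
        self,
        t_end: int,
        on_lick: Callable[[int], None] | None = None,
        on_tick: Callable[[int, int], bool] | None = None,
    ) -> bool:
        """Advance the clock to ``t_end`` stepping the agent.

        ``on_tick(t, direction)`` may return True to interrupt the interval
        (e.g. a completed ratio); the clock then stays at the interrupting
        step's time so consequence events land in the same millisecond as the
        completing tick.  Returns True if interrupted.
        """
        cfg = self.cfg
        step = self.mouse.step
        stim = self.stim
        dt = cfg.dt_ms
        while self.t < t_end:
            d = dt if self.t + dt <= t_end else t_end - self.t
            lick, dticks = step(self.t, d, stim)
            if lick and on_lick is not None:
                on_lick(self.t)
            if dticks and on_tick is not None:
                if on_tick(self.t, 1 if dticks > 0 else -1):
                    return True
            self.t += d
        return False

    def finish(self, extra_meta: dict | None = None) -> SessionLog:
        self.emit(E.SESSION_END)
        cfg = self.cfg
        meta = {
            "session_id": f"{cfg.task_kind}-{cfg.seed}",
            "task_kind": cfg.task_kind,
            "config_digest": config_digest(cfg),
            "seed": str(cfg.seed),
            "schema_version": str(SCHEMA_VERSION),
            "duration_ms": str(self.t),
            "access_ms": str(cfg.access_ms),
            "active_direction": str(cfg.active_direction),
            "ticks_per_rotation": str(cfg.ticks_per_rotation),
        }
        if extra_meta:
            meta.update({k: str(v) for k, v in extra_meta.items()})
        return SessionLog(metadata=meta, events=self.events)

    # -- shared building blocks ----------------------------------------------

    def deliver_pulses(self, t_end: int, on_lick=None) -> None:
        """Five (configurable) solenoid pulses at the inter-pulse interval,
        interleaved with agent stepping; pulses past ``t_end`` are dropped."""
        cfg = self.cfg
        t0 = self.t
        for k in range(cfg.pulses_per_reward):
            tp = t0 + k * cfg.inter_pulse_ms
            if tp >= t_end:
                return
            self.run_until(tp, on_lick=on_lick)
            self.emit(E.SOLENOID_OPEN, cfg.solution_index)


def run_session(cfg: SessionConfig, agent, plan: Sequence[TrialPlan] | None = None,
                rng: np.random.Generator | None = None):
    """Dispatch on ``cfg.task_kind``; returns what the task runner returns."""
    runners = {
        "free_access": run_free_access,
        "spout_training": run_spout_training,
        "operant_fr": run_operant_fr,
        "operant_pr": run_operant_pr,
        "opto_positive": run_opto_positive,
        "opto_negative": run_opto_negative,
        "wtp": run_wtp,
    }
    if cfg.task_kind == "multispout":
        if plan is None:
            from .scheduler import make_trial_plans
            plan = make_trial_plans(
                n_trials=cfg.n_trials, iti_lo_ms=cfg.iti_lo_ms, iti_hi_ms=cfg.iti_hi_ms,
                rng_seed=cfg.seed,
            )
        return run_multispout(cfg, agent, plan, rng)
    return runners[cfg.task_kind](cfg, agent, rng)


# ---------------------------------------------------------------------------
# lick-only tasks
# ---------------------------------------------------------------------------

def run_free_access(cfg: SessionConfig, agent, rng=None) -> SessionLog:
    """Closed-loop lick training: each lick triggers one pulse in the same ms."""
    assert cfg.task_kind == "free_access"
    s = _Session(cfg, agent, rng)
    s.stim.spout_available = True

    def on_lick(t: int) -> None:
        s.emit(E.LICK, 0)
        s.emit(E.SOLENOID_OPEN, cfg.solution_index)

    s.run_until(cfg.duration_ms, on_lick=on_lick)
    return s.finish()


def run_spout_training(cfg: SessionConfig, agent, rng=None) -> SessionLog:
    """Non-contingent trials: tone + five pulses per 5 s access period."""
    assert cfg.task_kind == "spout_training"
    s = _Session(cfg, agent, rng)

    def on_lick(t: int) -> None:
        s.emit(E.LICK, 0)

    for i in range(cfg.n_trials):
        s.emit(E.TRIAL_START, i)
        s.emit(E.SPOUT_EXTEND_CMD, 0)
        s.emit(E.TONE_ON, cfg.tone_hz)
        s.stim.spout_available = True
        t_end = s.t + cfg.access_ms
        s.deliver_pulses(t_end, on_lick=on_lick)
        s.run_until(t_end, on_lick=on_lick)
        s.emit(E.TONE_OFF)
        s.emit(E.SPOUT_RETRACT_CMD, 0)
        s.stim.spout_available = False
        s.emit(E.TRIAL_END, i)
        if i < cfg.n_trials - 1:
            s.run_until(s.t + sample_iti(cfg.iti_lo_ms, cfg.iti_hi_ms, s.rng))
    return s.finish({"n_trials": cfg.n_trials})


def run_multispout(cfg: SessionConfig, agent, plan: Sequence[TrialPlan], rng=None) -> SessionLog:
    """Brief-access consumption over a radial head of five spouts."""
    assert cfg.task_kind == "multispout"
    if cfg.n_trials and len(plan) != cfg.n_trials:
        raise ValueError(f"plan has {len(plan)} trials but config expects {cfg.n_trials}")
    s = _Session(cfg, agent, rng)
    for p in plan:
        s.emit(E.TRIAL_START, p.trial_index)
        s.emit(E.SPOUT_EXTEND_CMD, p.spout_index)
        s.stim.spout_available = True
        s.stim.solution = p.solution_index

        def on_lick(t: int, _p: TrialPlan = p) -> None:
            s.emit(E.LICK, _p.spout_index)
            s.emit(E.SOLENOID_OPEN, _p.solution_index)

        s.run_until(s.t + cfg.access_ms, on_lick=on_lick)
        s.emit(E.SPOUT_RETRACT_CMD, p.spout_index)
        s.stim.spout_available = False
        s.emit(E.TRIAL_END, p.trial_index)
        if p.trial_index < len(plan) - 1:
            s.run_until(s.t + p.iti_ms)
    spout_map = ",".join(
        f"{sol}:{spout}" for sol, spout in sorted({(p.solution_index, p.spout_index) for p in plan})
    )
    return s.finish({"n_trials": len(plan), "spout_map": spout_map})


# ---------------------------------------------------------------------------
# wheel operant tasks
# ---------------------------------------------------------------------------

def _ratio_ticks(turns: float, ticks_per_rotation: int) -> int:
    return max(1, round(turns * ticks_per_rotation))


def _run_operant(cfg: SessionConfig, agent, rng, costs: Sequence[float] | None,
                 timeout_ms: int | None):
    """Common FR/PR machine.

    ``costs`` is None for a fixed ratio (every reward costs
    ``fixed_ratio_turns``) or the progressive cost sequence; ``timeout_ms``
    is the no-reinforcer termination rule (progressive ratio only).
    """
    s = _Session(cfg, agent, rng)
    summary = OperantSummary()
    active_acc = 0
    inactive_acc = 0
    last_reinforcer_ms = 0
    brake_span_ms = cfg.brake_lead_ms + cfg.access_ms  # full rewarded-trial brake envelope

    def current_cost() -> float:
        if costs is None:
            return cfg.fixed_ratio_turns
        i = summary.n_reinforcers
        if i < len(costs):
            return costs[i]
        return ratio_schedule(cfg.pr_kind, i + 1).costs[i]

    def on_lick(t: int) -> None:
        s.emit(E.LICK, 0)

    interrupt = {"why": ""}

    def on_tick(t: int, direction: int) -> bool:
        nonlocal active_acc, inactive_acc
        s.emit(E.ROTATION_TICK, direction)
        if direction == cfg.active_direction:
            active_acc += 1
            summary.n_active_ticks += 1
            if active_acc >= _ratio_ticks(current_cost(), cfg.ticks_per_rotation):
                interrupt["why"] = "reward"
                return True
        else:
            inactive_acc += 1
            summary.n_inactive_ticks += 1
            if inactive_acc >= _ratio_ticks(current_cost(), cfg.ticks_per_rotation):
                interrupt["why"] = "timeout"
                return True
        return False

    while s.t < cfg.duration_ms:
        horizon = cfg.duration_ms
        if timeout_ms is not None:
            horizon = min(horizon, last_reinforcer_ms + timeout_ms)
        hit = s.run_until(horizon, on_tick=on_tick)
        if not hit:
            if timeout_ms is not None and horizon < cfg.duration_ms:
                break  # no-reinforcer timeout reached
            continue
        if interrupt["why"] == "reward":
            cost = current_cost()
            s.emit(E.BRAKE_ON)
            s.stim.braked = True
            s.run_until(min(s.t + cfg.brake_lead_ms, cfg.duration_ms))
            t_end = min(s.t + cfg.access_ms, cfg.duration_ms)
            s.emit(E.SPOUT_EXTEND_CMD, 0)
            s.emit(E.TONE_ON, cfg.tone_hz)
            s.stim.spout_available = True
            s.deliver_pulses(t_end, on_lick=on_lick)
            s.run_until(t_end, on_lick=on_lick)
            s.stim.spout_available = False
            if s.t < cfg.duration_ms:
                s.emit(E.TONE_OFF)
                s.emit(E.SPOUT_RETRACT_CMD, 0)
                s.emit(E.BRAKE_OFF)
            s.stim.braked = False
            summary.n_reinforcers += 1
            summary.breakpoint = cost
            last_reinforcer_ms = s.t
            if hasattr(s.mouse, "notify_reinforcer"):
                s.mouse.notify_reinforcer()
            active_acc = 0
        else:
            # inactive ratio: brake for the same total time as a rewarded
            # trial's brake envelope, with no spout, tone or delivery
            s.emit(E.BRAKE_ON)
            s.stim.braked = True
            s.run_until(min(s.t + brake_span_ms, cfg.duration_ms))
            if s.t < cfg.duration_ms:
                s.emit(E.BRAKE_OFF)
            s.stim.braked = False
            summary.n_timeouts += 1
            inactive_acc = 0

    summary.session_end_ms = s.t
    extra = {
        "fixed_ratio_turns": cfg.fixed_ratio_turns,
        "n_reinforcers": summary.n_reinforcers,
    }
    if costs is not None:
        extra["pr_kind"] = cfg.pr_kind
        extra["breakpoint"] = summary.breakpoint
    return s.finish(extra), summary


def run_operant_fr(cfg: SessionConfig, agent, rng=None) -> SessionLog:
    """Fixed-ratio operant conditioning for sucrose."""
    assert cfg.task_kind == "operant_fr"
    log, _ = _run_operant(cfg, agent, rng, costs=None, timeout_ms=None)
    return log


def run_operant_pr(cfg: SessionConfig, agent, rng=None) -> tuple[SessionLog, OperantSummary]:
    """Progressive-ratio session; ends at the duration cap or after
    ``pr_timeout_ms`` without a reinforcer, whichever comes first."""
    assert cfg.task_kind == "operant_pr"
    costs = ratio_schedule(cfg.pr_kind, 64).costs
    return _run_operant(cfg, agent, rng, costs=costs, timeout_ms=cfg.pr_timeout_ms)


# ---------------------------------------------------------------------------
# optogenetic reinforcement
# ---------------------------------------------------------------------------

def _run_opto(cfg: SessionConfig, agent, rng, positive: bool):
    s = _Session(cfg, agent, rng)
    ratio = _ratio_ticks(cfg.fixed_ratio_turns, cfg.ticks_per_rotation)
    active_acc = 0
    n_events = 0
    n_active = 0
    n_inactive = 0
    counting = True

    if not positive:
        s.emit(E.LASER_ON, cfg.laser_hz)
        s.stim.laser_on = True
        s.stim.laser_hz = cfg.laser_hz

    def on_tick(t: int, direction: int) -> bool:
        nonlocal active_acc, n_active, n_inactive
        s.emit(E.ROTATION_TICK, direction)
        if direction == cfg.active_direction:
            n_active += 1
            if counting:
                active_acc += 1
                return active_acc >= ratio
        else:
            n_inactive += 1
        return False

    span = cfg.stim_ms if positive else cfg.pause_ms
    while s.t < cfg.duration_ms:
        if not s.run_until(cfg.duration_ms, on_tick=on_tick):
            break
        # ratio complete: stimulation (positive) or stimulation pause (negative)
        if positive:
            s.emit(E.LASER_ON, cfg.laser_hz)
            s.stim.laser_on = True
            s.stim.laser_hz = cfg.laser_hz
        else:
            s.emit(E.LASER_OFF)
            s.stim.laser_on = False
        s.emit(E.TONE_ON, cfg.tone_hz)
        n_events += 1
        if hasattr(s.mouse, "notify_reinforcer"):
            s.mouse.notify_reinforcer()
        counting = False
        s.run_until(min(s.t + span, cfg.duration_ms), on_tick=on_tick)
        counting = True
        active_acc = 0
        if s.t < cfg.duration_ms:
            s.emit(E.TONE_OFF)
            if positive:
                s.emit(E.LASER_OFF)
                s.stim.laser_on = False
            else:
                s.emit(E.LASER_ON, cfg.laser_hz)
                s.stim.laser_on = True

    key = "n_stimulations" if positive else "n_pauses"
    meta = {key: n_events, "laser_hz": cfg.laser_hz,
            "n_active_ticks": n_active, "n_inactive_ticks": n_inactive}
    return s.finish(meta)


def run_opto_positive(cfg: SessionConfig, agent, rng=None) -> SessionLog:
    """Active rotation earns 1 s of laser stimulation + tone; rotation during
    the stimulation is logged but does not count toward the next one."""
    assert cfg.task_kind == "opto_positive"
    return _run_opto(cfg, agent, rng, positive=True)


def run_opto_negative(cfg: SessionConfig, agent, rng=None) -> SessionLog:
    """Continuous stimulation from session start; active rotation pauses the
    laser for 3 s (+ tone); rotation during a pause does not count."""
    assert cfg.task_kind == "opto_negative"
    return _run_opto(cfg, agent, rng, positive=False)


# ---------------------------------------------------------------------------
# wheel place preference
# ---------------------------------------------------------------------------

def run_wtp(cfg: SessionConfig, agent, rng=None) -> tuple[SessionLog, WtpSummary]:
    """Wheel place preference: two half-rotation zones, one laser-paired.

    Wheel position is tracked modulo one rotation; the paired zone is the
    half-circle of positions [0, half); the start position is the unpaired
    position adjacent to the paired-zone boundary.  Each zone has its own
    cue tone; entering the paired zone starts continuous stimulation.
    """
    assert cfg.task_kind == "wtp"
    s = _Session(cfg, agent, rng)
    n = cfg.ticks_per_rotation
    half = n // 2
    pos = n - 1  # unpaired, adjacent to the paired zone across the 0 boundary
    in_paired = False
    summary = WtpSummary()
    last_change = 0

    s.emit(E.TONE_ON, cfg.tone_hz_unpaired)
    s.stim.in_paired_zone = False

    def settle(t: int, paired_now: bool) -> None:
        nonlocal in_paired, last_change
        if paired_now:
            summary.unpaired_s += (t - last_change) / 1000.0
        else:
            summary.paired_s += (t - last_change) / 1000.0
        last_change = t
        in_paired = paired_now
        s.stim.in_paired_zone = paired_now
        summary.n_zone_entries += 1
        s.emit(E.ZONE_ENTER, 1 if paired_now else 0)
        s.emit(E.TONE_OFF)
        if paired_now:
            s.emit(E.TONE_ON, cfg.tone_hz)
            s.emit(E.LASER_ON, cfg.laser_hz)
            s.stim.laser_on = True
            s.stim.laser_hz = cfg.laser_hz
        else:
            s.emit(E.TONE_ON, cfg.tone_hz_unpaired)
            s.emit(E.LASER_OFF)
            s.stim.laser_on = False

    def on_tick(t: int, direction: int) -> bool:
        nonlocal pos
        s.emit(E.ROTATION_TICK, direction)
        pos = (pos + direction) % n
        paired_now = pos < half
        if paired_now != in_paired:
            settle(t, paired_now)
        return False

    s.run_until(cfg.duration_ms, on_tick=on_tick)
    if in_paired:
        summary.paired_s += (s.t - last_change) / 1000.0
    else:
        summary.unpaired_s += (s.t - last_change) / 1000.0
    log = s.finish({
        "laser_hz": cfg.laser_hz,
        "paired_s": f"{summary.paired_s:.3f}",
        "unpaired_s": f"{summary.unpaired_s:.3f}",
    })
    return log, summary
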