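"""Independent oracles and scripted agents shared across the test suite.

Everything here re-derives quantities by brute force, without going through
the code paths it is used to check.
"""

from __future__ import annotations

import numpy as np

from lickwheel.events import Event, EventCode, SessionLog

E = EventCode


class ConstantRotator:
    """Deterministic agent: one tick in ``direction`` per clock step, no licks."""

    def __init__(self, direction: int = 1):
        self.direction = direction

    def reset(self) -> None:
        pass

    def notify_reinforcer(self) -> None:
        pass

    def step(self, t_ms, dt_ms, stim):
        return False, self.direction


class MuteAgent:
    """Never licks, never moves."""

    def reset(self) -> None:
        pass

    def notify_reinforcer(self) -> None:
        pass

    def step(self, t_ms, dt_ms, stim):
        return False, 0


class ScriptedAgent:
    """Replays a fixed list of (lick, dticks) actions, then stays still."""

    def __init__(self, actions):
        self.actions = list(actions)
        self._i = 0

    def reset(self) -> None:
        self._i = 0

    def notify_reinforcer(self) -> None:
        pass

    def step(self, t_ms, dt_ms, stim):
        if self._i < len(self.actions):
            a = self.actions[self._i]
            self._i += 1
            return a
        return False, 0


def replay_reward_counts(log: SessionLog, ratio_ticks: int) -> tuple[int, int]:
    """Re-derive (rewards, inactive timeouts) from the raw tick stream.

    Walks the log counting ticks per direction between resets, excluding
    laser stimulation/pause windows; a reward or timeout occurs exactly when
    an accumulator reaches the ratio.  Brake windows need no exclusion
    because a braked wheel emits no ticks.
    """
    active_dir = int(log.metadata.get("active_direction", "1"))
    rewards = timeouts = 0
    acc_a = acc_i = 0
    excluded = False  # inside a stimulation or pause window
    laser_started_on = any(
        e.code is E.LASER_ON and e.time_ms == 0 for e in log.events
    )
    for e in log.events:
        if e.code is E.LASER_ON:
            excluded = False if laser_started_on else True
        elif e.code is E.LASER_OFF:
            excluded = True if laser_started_on else False
        elif e.code is E.ROTATION_TICK:
            if excluded:
                continue
            if e.value == active_dir:
                acc_a += 1
                if acc_a >= ratio_ticks:
                    rewards += 1
                    acc_a = 0
            else:
                acc_i += 1
                if acc_i >= ratio_ticks:
                    timeouts += 1
                    acc_i = 0
    return rewards, timeouts


def gap_scan_bouts(times, pause_ms):
    """Brute-force bout partition: numpy cut at every gap >= pause."""
    t = np.asarray(times)
    if t.size == 0:
        return []
    cut = np.flatnonzero(np.diff(t) >= pause_ms) + 1
    out = []
    for chunk in np.split(t, cut):
        out.append((int(chunk[0]), int(chunk[-1]), len(chunk)))
    return out


def all_latin_squares(n: int):
    """Exhaustively enumerate all n x n Latin squares (rows over symbols 0..n-1)."""
    from itertools import permutations

    perms = list(permutations(range(n)))
    squares = []

    def extend(rows):
        if len(rows) == n:
            squares.append(tuple(rows))
            return
        for p in perms:
            if all(all(p[j] != r[j] for j in range(n)) for r in rows):
                extend(rows + [p])

    extend([])
    return squares


def make_valid_log(rng: np.random.Generator, n_trials: int | None = None) -> SessionLog:
    """Random structurally valid trial log for round-trip property tests."""
    if n_trials is None:
        n_trials = int(rng.integers(0, 5))
    meta = {
        "session_id": "prop",
        "task_kind": "multispout",
        "config_digest": "0" * 8,
        "seed": "1",
        "schema_version": "1",
    }
    events = [Event(0, E.SESSION_START)]
    t = 0
    for i in range(n_trials):
        events.append(Event(t, E.TRIAL_START, i))
        events.append(Event(t, E.SPOUT_EXTEND_CMD, int(rng.integers(0, 5))))
        for _ in range(int(rng.integers(0, 4))):
            t += int(rng.integers(1, 500))
            events.append(Event(t, E.LICK, 0))
            events.append(Event(t, E.SOLENOID_OPEN, int(rng.integers(0, 5))))
        t += int(rng.integers(1, 3000))
        events.append(Event(t, E.SPOUT_RETRACT_CMD, 0))
        events.append(Event(t, E.TRIAL_END, i))
        t += int(rng.integers(1, 8000))
    events.append(Event(t + 1, E.SESSION_END))
    return SessionLog(metadata=meta, events=events)
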