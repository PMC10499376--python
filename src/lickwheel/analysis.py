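"""Behavioral readouts computed from session logs.

Covers lick microstructure (inter-lick intervals, bout segmentation),
per-trial consumption metrics, per-solution summaries across counterbalanced
sessions, wheel rotation summaries, progressive-ratio breakpoints, wheel
place-preference dwell times, optogenetic response counts, and within-subject
z-scoring across conditions.  Outputs are tidy pandas DataFrames (one row per
trial / per solution / per session).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .events import EventCode, SessionLog, iter_trials
from .scheduler import ratio_schedule

__all__ = [
    "LickBout",
    "inter_lick_intervals",
    "segment_bouts",
    "trial_table",
    "summarize_by_solution",
    "binned_trial_licks",
    "binned_lick_rate",
    "wheel_summary",
    "breakpoint_from_log",
    "wtp_dwell",
    "opto_counts",
    "zscore_across_conditions",
]

E = EventCode

DEFAULT_BOUT_PAUSE_MS = 1000  # gap closing a lick bout; convention, not printed

_TRIAL_TASKS = {"spout_training", "operant_fr", "operant_pr", "multispout"}


@dataclass(frozen=True)
class LickBout:
    start_ms: int
    end_ms: int
    n_licks: int


def inter_lick_intervals(log: SessionLog) -> list[int]:
    """Successive lick-time differences, within trial for trial-based tasks.

    For trial-based tasks intervals never span a trial boundary (the spout is
    retracted between trials, so cross-trial gaps are not licking rhythm).
    """
    if log.task_kind in _TRIAL_TASKS:
        ilis: list[int] = []
        for _, _, _, seg in iter_trials(log):
            t = [e.time_ms for e in seg if e.code is E.LICK]
            ilis.extend(b - a for a, b in zip(t, t[1:]))
        return ilis
    t = log.times(E.LICK)
    return [b - a for a, b in zip(t, t[1:])]


def segment_bouts(lick_times: Sequence[int], pause_ms: int = DEFAULT_BOUT_PAUSE_MS) -> list[LickBout]:
    """Partition sorted lick times into bouts; a gap >= ``pause_ms`` closes a bout."""
    lick_times = list(lick_times)
    if any(b < a for a, b in zip(lick_times, lick_times[1:])):
        raise ValueError("lick_times must be sorted")
    if not lick_times:
        return []
    bouts: list[LickBout] = []
    start = prev = lick_times[0]
    n = 1
    for t in lick_times[1:]:
        if t - prev >= pause_ms:
            bouts.append(LickBout(start, prev, n))
            start, n = t, 1
        else:
            n += 1
        prev = t
    bouts.append(LickBout(start, prev, n))
    return bouts


def _trial_solution(seg, spout_to_solution: dict[int, int]) -> int:
    for e in seg:
        if e.code is E.SOLENOID_OPEN:
            return e.value
    # no delivery this trial: infer from the extended spout via the session's
    # solution->spout map when the log carries one
    for e in seg:
        if e.code is E.SPOUT_EXTEND_CMD and e.value in spout_to_solution:
            return spout_to_solution[e.value]
    return 0


def _spout_to_solution(log: SessionLog) -> dict[int, int]:
    raw = log.metadata.get("spout_map", "")
    out: dict[int, int] = {}
    if raw:
        for pair in raw.split(","):
            sol, _, spout = pair.partition(":")
            out[int(spout)] = int(sol)
    return out


def trial_table(log: SessionLog, bout_pause_ms: int = DEFAULT_BOUT_PAUSE_MS) -> pd.DataFrame:
    """One row per trial: lick count, first-lick latency, bout end time.

    Latency is measured from the spout extension command to the first lick
    and is NaN on trials without a lick.  ``last_lick_in_bout_ms`` is the end
    of the bout containing the trial's first lick, relative to access onset.
    """
    if log.task_kind not in _TRIAL_TASKS:
        raise ValueError(f"trial_table requires a trial-based log, got {log.task_kind!r}")
    rows = []
    sp2sol = _spout_to_solution(log)
    for idx, _start, _end, seg in iter_trials(log):
        extend = next((e for e in seg if e.code is E.SPOUT_EXTEND_CMD), None)
        onset = extend.time_ms if extend is not None else _start
        spout = extend.value if extend is not None else 0
        licks = [e.time_ms for e in seg if e.code is E.LICK]
        solution = _trial_solution(seg, sp2sol)
        if licks:
            latency = licks[0] - onset
            bouts = segment_bouts(licks, bout_pause_ms)
            last_in_bout = bouts[0].end_ms - onset
        else:
            latency = math.nan
            last_in_bout = math.nan
        rows.append(
            {
                "trial_index": idx,
                "solution_index": solution,
                "spout_index": spout,
                "n_licks": len(licks),
                "latency_first_lick_ms": latency,
                "last_lick_in_bout_ms": last_in_bout,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trial_index", "solution_index", "spout_index", "n_licks",
            "latency_first_lick_ms", "last_lick_in_bout_ms",
        ],
    )


def summarize_by_solution(
    trial_tables: Sequence[pd.DataFrame],
    counterbalance: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-solution means across counterbalanced sessions.

    Each input table is one session.  Aggregation is by solution (not spout):
    per-session means are computed first and then averaged across sessions,
    so every session contributes equally.  ``counterbalance`` (the
    session x solution -> spout square) is accepted for provenance/validation:
    when given, each session's spout assignment is checked against it.
    """
    per_session = []
    for si, tt in enumerate(trial_tables):
        if counterbalance is not None:
            expect = counterbalance[si]
            seen = tt.groupby("solution_index")["spout_index"].agg(lambda s: s.iloc[0])
            for sol, spout in seen.items():
                if expect[sol] != spout:
                    raise ValueError(
                        f"session {si}: solution {sol} on spout {spout}, "
                        f"counterbalance table says {expect[sol]}"
                    )
        g = tt.groupby("solution_index")
        per_session.append(
            pd.DataFrame(
                {
                    "session": si,
                    "licks_per_trial": g["n_licks"].mean(),
                    "latency_ms": g["latency_first_lick_ms"].mean(),
                    "prop_trials_with_lick": g["n_licks"].apply(lambda s: (s > 0).mean()),
                }
            )
        )
    stacked = pd.concat(per_session).reset_index()
    out = (
        stacked.groupby("solution_index")[["licks_per_trial", "latency_ms", "prop_trials_with_lick"]]
        .mean()
        .reset_index()
    )
    return out


def binned_trial_licks(
    tt: pd.DataFrame, bin_trials: int = 10, per_solution: bool = False
) -> pd.DataFrame:
    """Mean licks per trial in consecutive bins of ``bin_trials`` trials."""
    df = tt.copy()
    df["bin"] = df["trial_index"] // bin_trials
    keys = ["bin", "solution_index"] if per_solution else ["bin"]
    return df.groupby(keys)["n_licks"].mean().reset_index(name="mean_licks")


def binned_lick_rate(
    tt: pd.DataFrame, log: SessionLog, bin_ms: int = 250
) -> pd.DataFrame:
    """Peri-access lick rate (Hz) per solution, binned from access onset."""
    access_ms = log.meta_int("access_ms", 3000)
    edges = np.arange(0, access_ms + bin_ms, bin_ms)
    rows = []
    counts: dict[int, np.ndarray] = {}
    n_trials: dict[int, int] = {}
    sp2sol = _spout_to_solution(log)
    for idx, _s, _e, seg in iter_trials(log):
        extend = next((e for e in seg if e.code is E.SPOUT_EXTEND_CMD), None)
        onset = extend.time_ms if extend is not None else _s
        sol = _trial_solution(seg, sp2sol)
        rel = [e.time_ms - onset for e in seg if e.code is E.LICK]
        h, _ = np.histogram(rel, bins=edges)
        counts[sol] = counts.get(sol, np.zeros(len(edges) - 1)) + h
        n_trials[sol] = n_trials.get(sol, 0) + 1
    for sol in sorted(counts):
        rate = counts[sol] / n_trials[sol] / (bin_ms / 1000.0)
        for k, r in enumerate(rate):
            rows.append({"solution_index": sol, "time_ms": int(edges[k]), "rate_hz": float(r)})
    return pd.DataFrame(rows, columns=["solution_index", "time_ms", "rate_hz"])


def wheel_summary(log: SessionLog) -> dict:
    """Cumulative wheel position and per-direction tick totals.

    ``active`` is the direction recorded in the log metadata.  Cumulative
    position is in ticks, signed (+ = active direction).
    """
    active_dir = log.meta_int("active_direction", 1)
    ticks = log.of(E.ROTATION_TICK)
    t = np.fromiter((e.time_ms for e in ticks), dtype=np.int64, count=len(ticks))
    d = np.fromiter((e.value for e in ticks), dtype=np.int64, count=len(ticks))
    cum = np.cumsum(d * active_dir)  # + = toward the active direction
    return {
        "times_ms": t,
        "cumulative_ticks": cum,
        "terminal_position_ticks": int(cum[-1]) if len(cum) else 0,
        "total_active_ticks": int(np.sum(d == active_dir)),
        "total_inactive_ticks": int(np.sum(d == -active_dir)),
    }


def breakpoint_from_log(log: SessionLog) -> float:
    """Cost (wheel turns) of the last completed progressive ratio.

    Reinforcer count is re-derived from solenoid pulse groups (one reward =
    one burst of ``pulses_per_reward`` pulses); 0 reinforcers -> breakpoint 0.
    """
    pr_kind = log.metadata.get("pr_kind", "semilog")
    pulse_times = log.times(E.SOLENOID_OPEN)
    if not pulse_times:
        return 0.0
    # group pulses into delivery bursts: a new reward starts whenever the gap
    # exceeds the inter-pulse interval
    gaps = np.diff(pulse_times)
    n_rewards = 1 + int(np.sum(gaps > 1000))
    return ratio_schedule(pr_kind, n_rewards).costs[n_rewards - 1]


def wtp_dwell(log: SessionLog) -> dict:
    """Seconds spent in each zone of the wheel place-preference task.

    Reconstructed from zone_enter events; paired + unpaired always equals the
    session duration.
    """
    if log.task_kind != "wtp":
        raise ValueError(f"wtp_dwell requires a wtp log, got {log.task_kind!r}")
    duration = log.duration_ms
    paired_ms = 0
    last_t = 0
    in_paired = False  # session starts in the unpaired zone
    n_entries = 0
    for e in log.events:
        if e.code is E.ZONE_ENTER:
            if in_paired:
                paired_ms += e.time_ms - last_t
            last_t = e.time_ms
            in_paired = e.value == 1
            n_entries += 1
    if in_paired:
        paired_ms += duration - last_t
    return {
        "paired_s": paired_ms / 1000.0,
        "unpaired_s": (duration - paired_ms) / 1000.0,
        "n_zone_entries": n_entries,
        "session_s": duration / 1000.0,
    }


def opto_counts(log: SessionLog) -> dict:
    """Stimulation/pause counts and per-direction response totals.

    For positive reinforcement each laser_on is one earned stimulation; for
    negative reinforcement each laser_off is one earned pause (the laser is
    on from session start).
    """
    active_dir = log.meta_int("active_direction", 1)
    n_on = len(log.times(E.LASER_ON))
    n_off = len(log.times(E.LASER_OFF))
    negative = bool(log.events) and any(
        e.code is E.LASER_ON and e.time_ms == 0 for e in log.events
    )
    ticks = [e.value for e in log.of(E.ROTATION_TICK)]
    return {
        "n_events": n_off if negative else n_on,
        "kind": "pause" if negative else "stimulation",
        "active_responses": sum(1 for d in ticks if d == active_dir),
        "inactive_responses": sum(1 for d in ticks if d == -active_dir),
    }


def zscore_across_conditions(values: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Within-subject z-scores across conditions.

    ``values`` is subjects x conditions.  Each row is centered and scaled by
    its own mean and sample SD (ddof=1), e.g. [1, 2, 3] -> [-1, 0, 1]; a
    constant row cannot be scaled and comes back as zeros with its flag set.

    Returns ``(z, constant_flags)``.
    """
    arr = np.asarray(values, dtype=float)
    one_d = arr.ndim == 1
    if one_d:
        arr = arr[None, :]
    if arr.shape[1] < 2:
        raise ValueError("need at least two conditions per subject")
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    flags = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    z = np.zeros_like(arr)
    ok = ~flags
    z[ok] = (arr[ok] - mean[ok]) / sd[ok]
    if one_d:
        return z[0], flags
    return z, flags
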