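"""Trial sequencing, inter-trial intervals, ratio schedules, counterbalancing.

Everything here is deterministic given a seed: identical seeds produce
bit-identical schedules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "TrialPlan",
    "RatioSchedule",
    "schedule_multispout",
    "counterbalance_spouts",
    "sample_iti",
    "ratio_schedule",
    "make_trial_plans",
    "plans_to_rows",
]

# First eight semilogarithmic progressive-ratio costs, in wheel turns.  These
# printed terms are normative; terms beyond them come from the fitted
# exponential continuation in ratio_schedule.
SEMILOG_PREFIX = (0.25, 0.5, 0.81, 1.21, 1.71, 2.3, 3.1, 4.1)


@dataclass(frozen=True)
class TrialPlan:
    trial_index: int
    solution_index: int
    spout_index: int
    iti_ms: int


@dataclass(frozen=True)
class RatioSchedule:
    kind: str  # "semilog" | "linear"
    costs: tuple[float, ...]  # wheel turns, strictly increasing

    def __post_init__(self) -> None:
        if not self.costs or self.costs[0] <= 0:
            raise ValueError("costs must be non-empty with costs[0] > 0")
        if any(b <= a for a, b in zip(self.costs, self.costs[1:])):
            raise ValueError("costs must be strictly increasing")


def schedule_multispout(
    n_trials: int,
    n_solutions: int,
    block_size: int,
    per_block: int,
    rng_seed: int,
) -> list[int]:
    """Pseudorandom solution sequence with fixed per-block composition.

    Within every consecutive block of ``block_size`` trials each solution
    appears exactly ``per_block`` times; order within a block is a seeded
    uniform shuffle, independent across blocks.  The default task uses 100
    trials of 5 solutions with two presentations of each solution per every
    10 trials.
    """
    if block_size != n_solutions * per_block:
        raise ValueError(
            f"block_size ({block_size}) must equal n_solutions*per_block "
            f"({n_solutions}*{per_block})"
        )
    if n_trials % block_size != 0:
        raise ValueError(f"n_trials ({n_trials}) must be divisible by block_size ({block_size})")
    rng = np.random.default_rng(rng_seed)
    block = np.repeat(np.arange(n_solutions), per_block)
    out: list[int] = []
    for _ in range(n_trials // block_size):
        out.extend(int(x) for x in rng.permutation(block))
    return out


def counterbalance_spouts(n: int, rng_seed: int) -> np.ndarray:
    """Latin-square assignment of solutions to spouts over ``n`` sessions.

    Returns an ``n x n`` integer array ``A`` with ``A[session, solution] ==
    spout``; every (spout, solution) pair occurs exactly once across the n
    sessions.  The square is a seeded random row/column/symbol permutation of
    the cyclic square, which is reproducible but not uniform over all Latin
    squares.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    base = (np.arange(n)[:, None] + np.arange(n)[None, :]) % n
    rows = rng.permutation(n)
    cols = rng.permutation(n)
    syms = rng.permutation(n)
    return syms[base[rows][:, cols]]


def sample_iti(lo_ms: int, hi_ms: int, rng: np.random.Generator) -> int:
    """One inter-trial interval, uniform over the closed interval [lo, hi] ms."""
    if lo_ms > hi_ms:
        raise ValueError(f"lo_ms ({lo_ms}) > hi_ms ({hi_ms})")
    return int(rng.integers(lo_ms, hi_ms + 1))


# scale anchoring the exponential continuation to the last printed term,
# so cost(8) from the rule equals SEMILOG_PREFIX[-1] exactly
_SEMILOG_SCALE = SEMILOG_PREFIX[-1] / (5.0 * math.exp(0.2 * len(SEMILOG_PREFIX)) - 5.0)


def _semilog_continuation(i: int) -> float:
    # exponential growth rule continuing the printed prefix (1-based i);
    # only the prefix itself is normative
    return round(_SEMILOG_SCALE * (5.0 * math.exp(0.2 * i) - 5.0), 2)


def ratio_schedule(kind: str, n: int) -> RatioSchedule:
    """First ``n`` wheel-turn costs of a progressive-ratio schedule.

    ``semilog`` reproduces the printed sequence 0.25, 0.5, 0.81, 1.21, 1.71,
    2.3, 3.1, 4.1 exactly and continues with a fitted exponential rule;
    ``linear`` increments by half a rotation per reinforcer (0.5, 1.0, ...).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "semilog":
        costs = [
            SEMILOG_PREFIX[i] if i < len(SEMILOG_PREFIX) else _semilog_continuation(i + 1)
            for i in range(n)
        ]
    elif kind == "linear":
        costs = [0.5 * (i + 1) for i in range(n)]
    else:
        raise ValueError(f"unknown ratio schedule kind {kind!r}")
    return RatioSchedule(kind=kind, costs=tuple(costs))


def make_trial_plans(
    n_trials: int = 100,
    n_solutions: int = 5,
    block_size: int = 10,
    per_block: int = 2,
    iti_lo_ms: int = 5000,
    iti_hi_ms: int = 10000,
    spout_map: Sequence[int] | None = None,
    rng_seed: int = 0,
) -> list[TrialPlan]:
    """Full multi-spout session plan: solution order, spout mapping, ITIs.

    ``spout_map[solution] -> spout`` is one row of a counterbalance square
    (identity when omitted).
    """
    solutions = schedule_multispout(n_trials, n_solutions, block_size, per_block, rng_seed)
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 1]).generate_state(1)[0])
    if spout_map is None:
        spout_map = list(range(n_solutions))
    return [
        TrialPlan(
            trial_index=i,
            solution_index=sol,
            spout_index=int(spout_map[sol]),
            iti_ms=sample_iti(iti_lo_ms, iti_hi_ms, rng),
        )
        for i, sol in enumerate(solutions)
    ]


def plans_to_rows(plans: Sequence[TrialPlan]) -> list[dict]:
    """Schedule as tidy rows (trial_index, solution_index, spout_index, iti_ms)."""
    return [
        {
            "trial_index": p.trial_index,
            "solution_index": p.solution_index,
            "spout_index": p.spout_index,
            "iti_ms": p.iti_ms,
        }
        for p in plans
    ]
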