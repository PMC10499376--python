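"""Parametric virtual mouse.

The agent turns the current actuator state (spout availability, active
solution, laser, zone tones) into two behavioral outputs per engine clock
step: whether a lick occurs in the step, and a signed wheel displacement in
encoder ticks.  It is the controllable ground truth for every engine and
analysis test: its licking is a bout-structured renewal process whose
bout-initiation rate is the per-solution palatability map, and its rotation
is a biased random walk modulated by reinforcement and, in the wheel
place-preference task, by stimulation-dependent zone drift.

Mouse licking is rhythmic at roughly 7-8 Hz, so the default within-bout
inter-lick interval is 140 ms with a modest coefficient of variation.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = ["AgentParams", "Stimuli", "VirtualMouse", "agent_step", "preset", "PRESET_NAMES"]


@dataclass(frozen=True)
class AgentParams:
    """Behavioral parameters of the virtual mouse.

    ``bout_init_rate_hz`` maps solution index -> bout initiation rate during
    spout access (the palatability map); a missing solution falls back to
    ``default_bout_init_rate_hz``.  ``zone_drift`` maps laser frequency (Hz)
    -> drift in [-1, 1]: positive values slow the animal inside the
    stimulation-paired zone (preference), negative values speed it up
    (avoidance).  ``reinforcement_gain`` multiplies the rotation rate after
    each earned reward or stimulation, capped at ``rot_gain_cap`` times
    baseline.
    """

    ili_mean_ms: float = 140.0
    ili_cv: float = 0.25
    bout_len_mean: float = 8.0
    bout_init_rate_hz: Mapping[int, float] = field(default_factory=dict)
    default_bout_init_rate_hz: float = 2.0
    rot_rate_ticks_per_s: float = 16.0
    active_bias: float = 0.5
    reinforcement_gain: float = 1.0
    rot_gain_cap: float = 3.0
    zone_drift: Mapping[int, float] = field(default_factory=dict)
    # half-life of a general within-session motivational decay applied to both
    # bout initiation and rotation rate; 0 disables it (stationary agent)
    satiation_halflife_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ili_mean_ms <= 0:
            raise ValueError("ili_mean_ms must be > 0")
        if not 0.0 <= self.active_bias <= 1.0:
            raise ValueError("active_bias must be in [0, 1]")
        for name in ("ili_cv", "bout_len_mean", "rot_rate_ticks_per_s", "default_bout_init_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def init_rate(self, solution: int) -> float:
        return float(self.bout_init_rate_hz.get(solution, self.default_bout_init_rate_hz))

    def drift(self, laser_hz: int) -> float:
        return float(self.zone_drift.get(laser_hz, 0.0))


class Stimuli:
    """Actuator state visible to the agent at one clock step.

    The engine mutates a single instance in place as actuators switch.
    ``in_paired_zone`` is None outside the wheel place-preference task.
    """

    __slots__ = ("spout_available", "solution", "braked", "laser_on", "laser_hz", "in_paired_zone")

    def __init__(self) -> None:
        self.spout_available = False
        self.solution = 0
        self.braked = False
        self.laser_on = False
        self.laser_hz = 0
        self.in_paired_zone: bool | None = None


class VirtualMouse:
    """Stateful agent: call :meth:`step` once per engine clock step."""

    def __init__(self, params: AgentParams, seed: int | None = None):
        self.params = params
        self.rng = random.Random(params.seed if seed is None else seed)
        p = params
        sigma2 = math.log(1.0 + p.ili_cv**2)
        self._ili_sigma = math.sqrt(sigma2)
        self._ili_mu = math.log(p.ili_mean_ms) - sigma2 / 2.0
        # geometric bout length with mean bout_len_mean (>= 1 lick)
        self._bout_q = max(0.0, 1.0 - 1.0 / max(p.bout_len_mean, 1.0))
        self.reset()

    def reset(self) -> None:
        self._licks_left = 0  # licks remaining in current bout (0 = idle)
        self._next_lick_ms: float = math.inf
        self._rot_gain = 1.0
        self._elapsed_s = 0.0

    # -- engine notifications -------------------------------------------------
    def notify_reinforcer(self) -> None:
        """Earned reward or stimulation: scale rotation rate (learning)."""
        self._rot_gain = min(self._rot_gain * self.params.reinforcement_gain, self.params.rot_gain_cap)

    # -- behavior -------------------------------------------------------------
    def _draw_ili(self) -> float:
        return self.rng.lognormvariate(self._ili_mu, self._ili_sigma)

    def _draw_bout_len(self) -> int:
        if self._bout_q <= 0.0:
            return 1
        u = self.rng.random()
        return 1 + int(math.log(u) / math.log(self._bout_q)) if u > 0 else 1

    def step(self, t_ms: int, dt_ms: int, stim: Stimuli) -> tuple[bool, int]:
        """Advance one clock step; return (lick_this_step, dticks)."""
        p = self.params
        rng = self.rng
        self._elapsed_s += dt_ms / 1000.0

        # --- licking: bout-structured renewal gated on spout availability ---
        lick = False
        if stim.spout_available:
            if self._licks_left > 0:
                if t_ms >= self._next_lick_ms:
                    lick = True
                    self._licks_left -= 1
                    self._next_lick_ms = t_ms + self._draw_ili() if self._licks_left else math.inf
            else:
                rate = p.init_rate(stim.solution)
                if p.satiation_halflife_s > 0:
                    rate *= 0.5 ** (self._elapsed_s / p.satiation_halflife_s)
                if rate > 0 and rng.random() < rate * dt_ms / 1000.0:
                    lick = True  # first lick of a new bout
                    self._licks_left = self._draw_bout_len() - 1
                    self._next_lick_ms = t_ms + self._draw_ili() if self._licks_left else math.inf
        else:
            # spout retracted mid-bout aborts the bout
            self._licks_left = 0
            self._next_lick_ms = math.inf

        # --- rotation: biased walk, one tick at most per step ---------------
        dticks = 0
        rate = p.rot_rate_ticks_per_s * self._rot_gain
        if p.satiation_halflife_s > 0:
            rate *= 0.5 ** (self._elapsed_s / p.satiation_halflife_s)
        if rate > 0.0 and not stim.braked:
            if stim.in_paired_zone is not None:
                d = p.drift(stim.laser_hz)
                if d != 0.0:
                    # preference slows movement inside the paired zone and
                    # speeds it outside; avoidance is the mirror image
                    rate *= (1.0 - 0.8 * d) if stim.in_paired_zone else (1.0 + 0.8 * d)
            pr = rate * dt_ms / 1000.0
            if rng.random() < pr:
                dticks = 1 if rng.random() < p.active_bias else -1
        return lick, dticks


def agent_step(mouse: VirtualMouse, t_ms: int, dt_ms: int, stim: Stimuli) -> tuple[bool, int]:
    """Functional alias for :meth:`VirtualMouse.step`."""
    return mouse.step(t_ms, dt_ms, stim)


_CONC_MAP = {0: 0.25, 1: 0.7, 2: 1.5, 3: 2.8, 4: 4.5}  # licks scale with concentration

_PRESETS: dict[str, AgentParams] = {
    # steadily improving operant responder: rotation rate grows with rewards
    "learner": AgentParams(
        active_bias=0.85, rot_rate_ticks_per_s=6.0, reinforcement_gain=1.08, rot_gain_cap=4.0,
        default_bout_init_rate_hz=3.0,
    ),
    # never licks, never turns the wheel
    "non_responder": AgentParams(
        rot_rate_ticks_per_s=0.0, default_bout_init_rate_hz=0.0, bout_init_rate_hz={},
    ),
    # symmetric random walker, insensitive to stimulation
    "indifferent": AgentParams(active_bias=0.5, rot_rate_ticks_per_s=32.0, zone_drift={}),
    # dwells in the stimulation-paired zone, more strongly at higher frequency
    "preferrer": AgentParams(
        active_bias=0.5, rot_rate_ticks_per_s=32.0,
        zone_drift={1: 0.1, 5: 0.3, 10: 0.5, 20: 0.75, 40: 0.9},
    ),
    # avoids the stimulation-paired zone
    "avoider": AgentParams(
        active_bias=0.5, rot_rate_ticks_per_s=32.0,
        zone_drift={1: -0.1, 5: -0.3, 10: -0.5, 20: -0.75, 40: -0.9},
    ),
    # licking scales monotonically with solution index (concentration)
    "concentration_tracker": AgentParams(
        bout_init_rate_hz=dict(_CONC_MAP), default_bout_init_rate_hz=0.25,
        rot_rate_ticks_per_s=4.0,
    ),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str, seed: int | None = None) -> AgentParams:
    """Documented phenotype presets (learner, preferrer, ...); deterministic."""
    try:
        params = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}") from None
    return replace(params, seed=seed) if seed is not None else params
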