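"""Session configuration: per-task defaults, key=value files, digests.

All timing constants live here.  Defaults encode the published task
parameterizations: 60-trial spout training with 5 s access and 20-40 s ITIs,
30 min fixed-ratio operant sessions with 3 s access and five ~1.5 uL pulses
at a 200 ms inter-pulse interval, progressive-ratio sessions capped at 1 h or
15 min without a reinforcer, 20 min optogenetic sessions (1 s stimulation for
positive reinforcement, 3 s pauses for negative reinforcement), 20 min wheel
place-preference sessions on a 64-tick encoder, and 100-trial multi-spout
sessions with 3 s access and 5-10 s uniform ITIs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Union

TASK_KINDS = (
    "free_access",
    "spout_training",
    "operant_fr",
    "operant_pr",
    "opto_positive",
    "opto_negative",
    "wtp",
    "multispout",
)

MINUTE_MS = 60_000


@dataclass(frozen=True)
class SessionConfig:
    """Complete parameterization of one task session."""

    task_kind: str
    duration_ms: int = 30 * MINUTE_MS
    n_trials: int = 0
    fixed_ratio_turns: float = 0.5
    access_ms: int = 3000
    pulses_per_reward: int = 5
    inter_pulse_ms: int = 200
    pulse_volume_ul: float = 1.5  # bookkeeping only
    iti_lo_ms: int = 5000
    iti_hi_ms: int = 10000
    tone_hz: int = 5000
    tone_hz_unpaired: int = 10000  # second zone tone in wheel place preference
    stim_ms: int = 1000
    pause_ms: int = 3000
    laser_hz: int = 20
    ticks_per_rotation: int = 64
    pr_kind: str = "semilog"
    pr_timeout_ms: int = 15 * MINUTE_MS
    active_direction: int = 1
    brake_lead_ms: int = 0  # brake engagement lead before spout extension
    dt_ms: int = 10  # engine clock step
    solution_index: int = 0  # delivered solution in single-solution tasks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task_kind not in TASK_KINDS:
            raise ValueError(f"unknown task_kind {self.task_kind!r}; one of {TASK_KINDS}")
        for name in ("duration_ms", "access_ms", "inter_pulse_ms", "stim_ms", "pause_ms", "dt_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.fixed_ratio_turns <= 0:
            raise ValueError("fixed_ratio_turns must be > 0")
        if self.ticks_per_rotation < 2 or self.ticks_per_rotation % 2:
            raise ValueError("ticks_per_rotation must be even and >= 2")
        if self.active_direction not in (-1, 1):
            raise ValueError("active_direction must be +1 or -1")
        if self.iti_lo_ms > self.iti_hi_ms:
            raise ValueError("iti_lo_ms > iti_hi_ms")


_TASK_DEFAULTS: dict[str, dict] = {
    "free_access": dict(duration_ms=10 * MINUTE_MS),
    "spout_training": dict(
        n_trials=60, access_ms=5000, iti_lo_ms=20_000, iti_hi_ms=40_000,
        duration_ms=60 * MINUTE_MS,
    ),
    "operant_fr": dict(duration_ms=30 * MINUTE_MS, fixed_ratio_turns=0.5, access_ms=3000),
    "operant_pr": dict(
        duration_ms=60 * MINUTE_MS, pr_timeout_ms=15 * MINUTE_MS, pr_kind="semilog",
        access_ms=3000,
    ),
    "opto_positive": dict(duration_ms=20 * MINUTE_MS, fixed_ratio_turns=0.5, stim_ms=1000),
    "opto_negative": dict(duration_ms=20 * MINUTE_MS, fixed_ratio_turns=0.5, pause_ms=3000),
    "wtp": dict(duration_ms=20 * MINUTE_MS),
    "multispout": dict(n_trials=100, access_ms=3000, iti_lo_ms=5000, iti_hi_ms=10_000,
                       duration_ms=30 * MINUTE_MS),
}


def default_config(task_kind: str, **overrides) -> SessionConfig:
    """The published parameterization for ``task_kind``, with overrides."""
    if task_kind not in _TASK_DEFAULTS:
        raise ValueError(f"unknown task_kind {task_kind!r}; one of {TASK_KINDS}")
    kw = dict(_TASK_DEFAULTS[task_kind])
    kw.update(overrides)
    return SessionConfig(task_kind=task_kind, **kw)


def config_digest(cfg: SessionConfig) -> str:
    """Short stable digest of every config field, for log provenance."""
    parts = "|".join(f"{f.name}={getattr(cfg, f.name)!r}" for f in fields(cfg))
    return hashlib.sha1(parts.encode()).hexdigest()[:8]


# -- flat key=value files -----------------------------------------------------

def _parse_scalar(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def read_kv(path: Union[str, Path]) -> dict:
    """Parse a flat ``key=value`` text file (``#`` comments, blank lines ok)."""
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, val = line.partition("=")
        out[key.strip()] = _parse_scalar(val.strip())
    return out


def write_kv(mapping: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(
        "".join(f"{k}={v}\n" for k, v in mapping.items()), encoding="utf-8"
    )


def load_config(path: Union[str, Path]) -> SessionConfig:
    """Read a SessionConfig from a key=value file (task_kind required)."""
    kv = read_kv(path)
    if "task_kind" not in kv:
        raise ValueError(f"{path}: missing task_kind")
    task_kind = str(kv.pop("task_kind"))
    valid = {f.name for f in fields(SessionConfig)}
    unknown = set(kv) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return default_config(task_kind, **kv)


def save_config(cfg: SessionConfig, path: Union[str, Path]) -> None:
    write_kv({f.name: getattr(cfg, f.name) for f in fields(cfg)}, path)


def with_seed(cfg: SessionConfig, seed: int) -> SessionConfig:
    return replace(cfg, seed=seed)


# -- agent parameter files ----------------------------------------------------

def _fmt_map(m) -> str:
    return ",".join(f"{k}:{v}" for k, v in sorted(dict(m).items()))


def _parse_map(text: str) -> dict[int, float]:
    out: dict[int, float] = {}
    if text:
        for pair in text.split(","):
            k, _, v = pair.partition(":")
            out[int(k)] = float(v)
    return out


def load_agent_params(path: Union[str, Path]):
    """Read AgentParams from a key=value file; mapping fields use k:v,k:v."""
    from .agent import AgentParams

    kv = read_kv(path)
    for key in ("bout_init_rate_hz", "zone_drift"):
        if key in kv:
            kv[key] = _parse_map(str(kv[key]))
    valid = {f.name for f in fields(AgentParams)}
    unknown = set(kv) - valid
    if unknown:
        raise ValueError(f"{path}: unknown agent parameter keys {sorted(unknown)}")
    return AgentParams(**kv)


def save_agent_params(params, path: Union[str, Path]) -> None:
    out = {}
    for f in fields(params):
        val = getattr(params, f.name)
        out[f.name] = _fmt_map(val) if isinstance(val, dict) else val
    write_kv(out, path)
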