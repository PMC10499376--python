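"""Synthetic two-channel fiber photometry and its processing chain.

The generator emulates a fluorescent-sensor recording during the multi-spout
task: the sensor channel carries a slow session-long drift (photobleaching),
per-trial double-exponential transients whose amplitude scales with the
delivered solution and with licking, and white noise; the control channel
carries drift and noise only.  The processing chain, applied in order, is

    polynomial detrend -> session z-score -> peri-event resampling to
    20 samples/s -> baseline shift on the 3 s before access onset ->
    mean/peak access-period summaries -> trial-wise behavior correlation.

The control channel is used to check for event-locked artifacts but is never
subtracted from the sensor channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import trial_table
from .events import EventCode, SessionLog

__all__ = [
    "RawTrace",
    "PETH",
    "PhotometryParams",
    "synth_trace",
    "detrend",
    "zscore_session",
    "build_peth",
    "access_summary",
    "behavior_correlation",
    "access_onsets",
]


@dataclass
class RawTrace:
    """Two-channel analog trace sampled at ``fs_hz``, t=0 at session start."""

    fs_hz: float
    sig: np.ndarray  # sensor channel (465 nm analog)
    ctrl: np.ndarray  # control channel (405 nm analog)

    def __post_init__(self) -> None:
        self.sig = np.asarray(self.sig, dtype=float)
        self.ctrl = np.asarray(self.ctrl, dtype=float)
        if self.sig.shape != self.ctrl.shape:
            raise ValueError("sig and ctrl must have equal length")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.sig)) / self.fs_hz


@dataclass
class PETH:
    """Trials x timepoints matrix of processed fluorescence at 20 samples/s."""

    z: np.ndarray  # trials x timepoints
    times_s: np.ndarray  # relative to access onset; spans [-pre_s, post_s]
    annotations: pd.DataFrame  # per-trial solution_index, n_licks

    def __post_init__(self) -> None:
        if self.z.shape[0] != len(self.annotations):
            raise ValueError("one annotation row per trial required")
        if self.z.shape[1] != len(self.times_s):
            raise ValueError("time axis must match matrix columns")


@dataclass(frozen=True)
class PhotometryParams:
    """Generator parameters for :func:`synth_trace`.

    ``transient_amp`` maps solution index -> transient amplitude (arbitrary
    fluorescence units); ``lick_coupling`` adds amplitude per lick in the
    trial.  ``tau_rise_s``/``tau_decay_s`` shape the double-exponential
    kernel.  ``drift_coeffs`` are polynomial coefficients (constant first)
    evaluated over normalized session time [0, 1].
    """

    drift_coeffs: tuple[float, ...] = (100.0, -8.0, -4.0, 2.0)
    transient_amp: Mapping[int, float] = field(default_factory=lambda: {0: 0.5, 1: 1.0, 2: 2.0, 3: 3.0, 4: 4.0})
    lick_coupling: float = 0.05
    tau_rise_s: float = 0.2
    tau_decay_s: float = 1.0
    noise_sd: float = 0.3
    ctrl_gain: float = 0.6  # drift amplitude ratio of control vs sensor channel
    fs_hz: float = 100.0
    seed: int = 0


def access_onsets(log: SessionLog) -> np.ndarray:
    """Access-period onset times (ms): spout extension command per trial."""
    return np.asarray(log.times(EventCode.SPOUT_EXTEND_CMD), dtype=np.int64)


def synth_trace(log: SessionLog, params: PhotometryParams = PhotometryParams()) -> RawTrace:
    """Generate a synthetic sensor/control recording aligned to a session log.

    sig = drift + per-trial transients + noise; ctrl = scaled drift + noise.
    Transient amplitude for a trial is ``transient_amp[solution] +
    lick_coupling * n_licks``.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.fs_hz
    n = int(np.ceil(log.duration_ms / 1000.0 * fs)) + 1
    t = np.arange(n) / fs
    x = t / t[-1] if t[-1] > 0 else t
    drift = np.polynomial.polynomial.polyval(x, params.drift_coeffs)

    sig = drift + rng.normal(0.0, params.noise_sd, n)
    ctrl = params.ctrl_gain * drift + rng.normal(0.0, params.noise_sd, n)

    tt = trial_table(log)
    onsets = access_onsets(log)
    # double-exponential kernel, peak-normalized
    kt = np.arange(0, int(8 * params.tau_decay_s * fs)) / fs
    kern = np.exp(-kt / params.tau_decay_s) - np.exp(-kt / params.tau_rise_s)
    peak = kern.max()
    if peak > 0:
        kern /= peak
    for onset_ms, (_, row) in zip(onsets, tt.iterrows()):
        amp = params.transient_amp.get(int(row["solution_index"]), 0.0)
        amp += params.lick_coupling * float(row["n_licks"])
        if amp == 0.0:
            continue
        i0 = int(round(onset_ms / 1000.0 * fs))
        seg = slice(i0, min(i0 + len(kern), n))
        sig[seg] += amp * kern[: seg.stop - seg.start]
    return RawTrace(fs_hz=fs, sig=sig, ctrl=ctrl)


def detrend(trace: RawTrace) -> RawTrace:
    """Subtract a least-squares cubic fitted over the whole session,
    independently per channel (bleaching correction)."""

    def _one(y: np.ndarray) -> np.ndarray:
        coefs = np.polynomial.polynomial.Polynomial.fit(trace.times_s, y, deg=3)
        return y - coefs(trace.times_s)

    return RawTrace(fs_hz=trace.fs_hz, sig=_one(trace.sig), ctrl=_one(trace.ctrl))


def zscore_session(trace: RawTrace) -> RawTrace:
    """Normalize each channel by the mean and SD of the entire session."""

    def _one(y: np.ndarray) -> np.ndarray:
        sd = y.std()
        if sd == 0 or not np.isfinite(sd):
            raise ValueError("cannot z-score a constant channel")
        return (y - y.mean()) / sd

    return RawTrace(fs_hz=trace.fs_hz, sig=_one(trace.sig), ctrl=_one(trace.ctrl))


def build_peth(
    trace: RawTrace,
    log: SessionLog,
    pre_s: float = 5.0,
    post_s: float = 5.0,
    fs_out: float = 20.0,
    baseline_s: float = 3.0,
    channel: str = "sig",
) -> PETH:
    """Peri-event matrix around access onsets, resampled to 20 samples/s.

    Each trial's samples are linearly interpolated onto a grid spanning
    [-pre_s, post_s] at ``fs_out``, then shifted so the mean over the
    ``baseline_s`` seconds before onset is zero.
    """
    if pre_s < baseline_s:
        raise ValueError("pre_s must cover the baseline window")
    y = getattr(trace, channel)
    t = trace.times_s
    grid = np.arange(round(-pre_s * fs_out), round(post_s * fs_out) + 1) / fs_out
    onsets_s = access_onsets(log) / 1000.0
    rows = np.empty((len(onsets_s), len(grid)))
    for i, t0 in enumerate(onsets_s):
        rows[i] = np.interp(t0 + grid, t, y)
    base = (grid >= -baseline_s) & (grid < 0)
    rows -= rows[:, base].mean(axis=1, keepdims=True)
    ann = trial_table(log)[["trial_index", "solution_index", "n_licks"]].reset_index(drop=True)
    return PETH(z=rows, times_s=grid, annotations=ann)


def access_summary(peth: PETH, access_s: float = 3.0) -> pd.DataFrame:
    """Per-trial mean and peak signal during the access period [0, access_s]."""
    win = (peth.times_s >= 0) & (peth.times_s <= access_s)
    out = peth.annotations.copy()
    out["mean_z"] = peth.z[:, win].mean(axis=1)
    out["peak_z"] = peth.z[:, win].max(axis=1)
    return out


def behavior_correlation(mean_z: Sequence[float], n_licks: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation between trial-wise signal and licking.

    Returns ``(r, p)`` with a two-sided p value.
    """
    res = stats.pearsonr(np.asarray(mean_z, float), np.asarray(n_licks, float))
    return float(res.statistic), float(res.pvalue)


def write_trace(trace: RawTrace, path) -> None:
    """Two-column CSV (sig, ctrl) with a ``# fs_hz=`` header line."""
    from pathlib import Path

    lines = [f"# fs_hz={trace.fs_hz}", "sig,ctrl"]
    lines.extend(f"{float(s)!r},{float(c)!r}" for s, c in zip(trace.sig, trace.ctrl))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trace(path) -> RawTrace:
    from pathlib import Path

    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("# fs_hz="):
        raise ValueError(f"{path}: missing '# fs_hz=' header")
    fs = float(lines[0].partition("=")[2])
    sig, ctrl = [], []
    for line in lines[2:]:
        if not line:
            continue
        a, _, b = line.partition(",")
        sig.append(float(a))
        ctrl.append(float(b))
    return RawTrace(fs_hz=fs, sig=np.array(sig), ctrl=np.array(ctrl))


def peth_long_format(peth: PETH) -> pd.DataFrame:
    """PETH as tidy long-format rows (trial, time_s, z, solution, n_licks)."""
    n_tr, n_t = peth.z.shape
    ann = peth.annotations
    return pd.DataFrame(
        {
            "trial_index": np.repeat(ann["trial_index"].to_numpy(), n_t),
            "time_s": np.tile(peth.times_s, n_tr),
            "z": peth.z.ravel(),
            "solution_index": np.repeat(ann["solution_index"].to_numpy(), n_t),
            "n_licks": np.repeat(ann["n_licks"].to_numpy(), n_t),
        }
    )
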