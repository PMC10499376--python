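# Methods

## The simulated platform

`lickwheel` models a head-fixed behavioral rig as a discrete-event system: a
millisecond clock, six actuators (retractable/radial lick spout, solenoid
valve, wheel brake, tone generator, laser, rotary encoder) and one state
machine per task. The engine advances in clock steps of `dt_ms`
(default 10 ms), querying the virtual mouse once per step for a lick and a
signed wheel displacement, and stamps every actuator and behavioral event
with an integer millisecond timestamp. Timing constants that the tasks
prescribe exactly — 200 ms inter-pulse intervals, 3 s and 5 s access
periods, 1 s stimulations, 3 s pauses — are scheduled exactly, independent
of the clock step; only agent behavior is quantized to the step. All
sessions are bit-reproducible: one session seed derives (via
`numpy.random.SeedSequence`) separate streams for engine-level draws
(inter-trial intervals) and for the agent.

Wheel geometry uses a 64-tick encoder per rotation for every wheel task; a
fixed ratio of *c* turns costs `round(64·c)` ticks (so the semilog cost 0.81
is 52 ticks). Excess ticks beyond a just-completed ratio are discarded — the
brake engages in the same millisecond as the completing tick — and ticks
during a brake do not exist (a braked wheel cannot move), while ticks during
laser stimulation or a stimulation pause are logged but excluded from ratio
accumulation. An inactive-direction ratio completion engages the brake for
the same envelope as a rewarded trial (brake lead + access period, 3 s by
default) with no spout, tone or delivery. Reversal training is a sign flip
of `active_direction`, not a separate machine.

In wheel place preference the circumference splits into two half-rotation
zones; positions `[0, 32)` are laser-paired and the session starts at
position 63 — the unpaired position adjacent to the paired boundary. Zone
crossings emit `zone_enter` events, toggle the zone tones (5 kHz paired,
10 kHz unpaired) and switch the laser, so paired + unpaired dwell always
equals the session duration exactly.

## The virtual mouse

The agent is deliberately phenomenological: it supplies controllable ground
truth, not a decision model.

- **Licking** is a bout-structured renewal process gated on spout
  availability. Bouts initiate as a Poisson process whose rate is the
  per-solution palatability map (`bout_init_rate_hz`); bout length is
  geometric with mean `bout_len_mean` (default 8 licks); within-bout
  inter-lick intervals are log-normal with mean `ili_mean_ms` (default
  140 ms ≈ the rhythmic 7–8 Hz licking of mice) and CV `ili_cv`
  (default 0.25). Spout retraction aborts a bout; licks cannot register
  while the spout is retracted.
- **Rotation** is a biased random walk: at most one tick per clock step,
  with probability `rate·dt` and direction `active_bias`. Earned rewards or
  stimulations multiply the rate by `reinforcement_gain` (capped), which is
  how the `learner` preset models acquisition. In place preference,
  `zone_drift(laser_hz) ∈ [−1, 1]` slows the walk inside the paired zone and
  speeds it outside (preference), or the mirror image (avoidance) — the
  classic occupancy mechanism by which dwell time scales inversely with
  local speed.
- An optional **motivational decay** halves both rates every
  `satiation_halflife_s`; it is off by default so engine tests see
  stationary agents.

What the agent does *not* emulate: deliberative pausing and grooming bouts,
effort-based quitting (so progressive-ratio breakpoints of a tireless
default agent reflect the 15-min no-reinforcer rule rather than motivation —
the progressive-ratio example adds fatigue for a realistic breakpoint),
satiety feedback from volume consumed, and any learning beyond the
reinforcement-gain ramp. Passing tests therefore demonstrate that the task
logic and analyses are correct and mutually consistent, not that real mice
behave like the agent.

## Schedules

Multi-spout pseudorandomization shuffles each block independently (two of
each of five solutions per 10-trial block); no cross-block anti-repeat
constraint is imposed. Counterbalancing samples a Latin square by random
row, column and symbol permutation of the cyclic square — reproducible and
valid, though not uniform over all Latin squares. Inter-trial intervals are
uniform over the closed millisecond interval (5–10 s multi-spout, 20–40 s
spout training). The semilogarithmic progressive-ratio costs use the printed
eight-term prefix verbatim (0.25 … 4.1 turns); beyond it, an exponential
growth rule `round₂(k·(5·e^{0.2 i} − 5))` continues the sequence, with *k*
anchored so the rule passes through the last prefix term. Only the prefix is
normative; the continuation is a deterministic, strictly increasing
extension.

## Photometry

The generator emulates a dopamine-sensor recording during the multi-spout
task at 100 Hz: a cubic bleaching drift (coefficients over normalized
session time), per-trial double-exponential transients (τ_rise 0.2 s,
τ_decay 1 s) whose amplitude is `transient_amp[solution] +
lick_coupling·n_licks`, and white noise (SD 0.3). The control channel
carries scaled drift and noise only, which is what makes the
no-event-locked-structure check meaningful. The processing chain is applied
strictly in order: least-squares cubic subtraction over the full session per
channel; z-scoring by the session mean and SD (a constant channel is an
error, not NaN); linear interpolation of each peri-event window onto a
20 samples/s grid spanning [−5 s, +5 s] by default; per-trial baseline shift
by the mean over [−3 s, 0); then mean/peak over the access window and
Pearson correlation against trial lick counts. Resampling by linear
interpolation is a deliberate choice — the simplest deterministic method —
and the window extents are parameters. When a window precedes the recording
start (the first trial begins at t = 0), interpolation clamps to the first
sample. The control channel is never subtracted from the sensor channel.

## Analysis conventions

- Bout criterion: a gap ≥ 1000 ms closes a bout. No printed criterion
  exists; 1 s is the common convention and the parameter is exposed
  everywhere it matters.
- First-lick latency is measured from the spout extension command; it is
  absent (NaN) on trials without a lick.
- `last_lick_in_bout_ms` is the end of the bout containing the trial's first
  lick, relative to access onset.
- Per-solution summaries compute per-session means first, then average
  across sessions, so each counterbalanced session contributes equally; the
  optional counterbalance square is validated against the logs rather than
  trusted.
- Within-subject z-scores across conditions use the sample SD (ddof = 1), so
  [1, 2, 3] → [−1, 0, 1]; constant condition vectors return zeros with a
  flag.
- Inter-lick intervals never span a trial boundary in trial-based tasks.
- Trial solution identity is read from the delivered solution when the trial
  had licks and otherwise from the session's solution→spout map recorded in
  the log metadata.

## Event-log format

One CSV per session: `#`-prefixed `key=value` metadata lines, a
`time_ms,code,value` header, then one event per row, UTF-8, LF newlines.
The code enumeration is closed (16 codes) and a `schema_version` metadata
field allows evolution; no attempt is made at byte compatibility with any
particular acquisition firmware, whose serial protocols are not part of this
package. Validation checks monotone non-negative timestamps, exactly one
session start/end, strict trial alternation with consecutive indices, on/off
alternation per actuator family (a trailing *on* is terminated by session
end), and the impossibility of encoder ticks while braked. Violations are
returned as data; writing an invalid log is refused.

## Problem sizes and determinism of the checks

The test suite simulates full-length sessions where the protocol's structure
is the point (60-trial spout training, 100-trial multi-spout, 30-min operant,
20-min place preference) and shorter sessions where only the contingency
matters. Stochastic expectations use seeded Monte-Carlo at sizes chosen for
stable estimates: the symmetric-agent dwell check averages 60 sessions in
the test suite and 200 in the acceptance script, with tolerance tied to the
measured standard error; the inter-lick-interval recovery uses a 20-min
free-access session (>500 within-bout intervals). Hand-computed expectations
live in a frozen five-trial fixture log. Closed-form oracles for reward and
stimulation counts hold exactly for deterministic constant-rate agents
because agent behavior is quantized to the clock step.
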