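# lickwheel

A hardware-free simulator and analysis toolkit for head-fixed operant,
consummatory and place-preference behavior on a running wheel.

Open-source head-fixed behavior platforms drive a small set of actuators — a
retractable lick spout, solenoid fluid valves, a wheel brake, tones and a
laser — from task state machines, and record every hardware and behavioral
event with millisecond timestamps. `lickwheel` re-implements that control
logic as a discrete-event simulator: each task state machine consumes the
actions of a parametric **virtual mouse** and emits a timestamped event log,
and an analysis layer computes every standard behavioral and photometry
readout from those logs. Because the virtual mouse's parameters are known
ground truth, every analysis function can be validated by parameter
recovery — which is the package's purpose: a fully testable, reproducible
model of the task logic and analysis chain, for method development,
pipeline validation and teaching.

## Task repertoire

| task | contingency | key timing |
|---|---|---|
| `free_access` | each lick triggers one ~1.5 µL pulse | 10 min |
| `spout_training` | non-contingent tone + 5 pulses per trial | 60 trials, 5 s access, 20–40 s ITI, 200 ms inter-pulse |
| `operant_fr` | active rotation earns sucrose; inactive rotation earns an equal brake | 30 min, FR 1/4–1 turn, 3 s access |
| `operant_pr` | progressive cost per reward | 1 h cap, or 15 min without a reinforcer |
| `opto_positive` | active rotation earns 1 s laser + tone | 20 min |
| `opto_negative` | active rotation pauses continuous laser 3 s | 20 min |
| `wtp` | half the wheel paired with continuous laser, zone tones | 20 min, 64 ticks/rotation |
| `multispout` | licks deliver one of five solutions | 100 trials, 3 s access, 5–10 s ITI |

The progressive-ratio cost sequence is either linear (0.5, 1.0, 1.5, … wheel
turns) or semilogarithmic (0.25, 0.5, 0.81, 1.21, 1.71, 2.3, 3.1, 4.1, …),
and the **breakpoint** — the cost of the last completed ratio — indexes
motivation. Multi-spout sessions are pseudorandomized (two presentations of
each solution per 10-trial block) with solution-to-spout pairings
counterbalanced over five sessions by a Latin square. The photometry module
generates a synthetic two-channel sensor recording and applies the standard
chain: cubic polynomial detrend, session-wide z-score, peri-event matrices
resampled to 20 samples/s, baseline shift on the 3 s before access onset,
mean/peak access-period summaries and trial-wise Pearson correlation with
licking (the control channel is checked for event-locked artifacts, never
subtracted).

## Worked example

Five counterbalanced brief-access sessions with a virtual mouse whose
bout-initiation rate rises with solution index (a concentration gradient):

```bash
python examples/02_multispout_palatability.py
```

```
per-solution means over 5 counterbalanced sessions (100 trials each):
 solution_index  licks_per_trial  latency_ms  prop_trials_with_lick
              0             3.99     1132.39                   0.61
              1             8.26      867.40                   0.85
              2            13.03      655.09                   0.99
              3            16.82      337.20                   1.00
              4            18.41      185.50                   1.00
```

Licks per trial rise, and first-lick latency falls, monotonically with
solution index: the analysis aggregates by solution across the
counterbalanced sessions (not by spout), so the palatability gradient the
agent was built with is recovered despite the spout rotation. The other
examples run operant and progressive-ratio sessions (`01`), wheel place
preference across stimulation frequencies (`03`, dwell above 600 s of the
1200 s session indicates preference), and the photometry chain (`04`, which
prints per-solution mean z-scores in generator order and a positive
trial-wise signal–lick correlation).

A thin CLI wraps the same library:

```bash
lickwheel simulate --task-kind multispout --seed 5 --out runs/ms5
lickwheel analyze --logs runs/ms5/log.csv --out runs/ms5/metrics
lickwheel demo-photometry --seed 2 --out runs/demo
```

Event logs are single-file CSVs (`#`-prefixed metadata, then
`time_ms,code,value` rows) that round-trip bit-exactly; identical seeds give
byte-identical sessions.

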