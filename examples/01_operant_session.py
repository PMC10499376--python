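"""Fixed- and progressive-ratio operant sessions on the wheel.

Simulates a 30 min fixed-ratio session (half a rotation per reward) and a
progressive-ratio session under the semilogarithmic cost schedule, then
summarizes rotation and motivation readouts.
"""

import lickwheel as lw
from lickwheel import analysis

# a mouse that responds more vigorously after each earned reward
agent = lw.preset("learner")

cfg = lw.default_config("operant_fr", seed=7)
log = lw.run_operant_fr(cfg, agent)
ws = analysis.wheel_summary(log)
print("fixed ratio 1/2 turn, 30 min:")
print(f"  rewards earned:        {log.metadata['n_reinforcers']}")
print(f"  active ticks:          {ws['total_active_ticks']}")
print(f"  inactive ticks:        {ws['total_inactive_ticks']}")
print(f"  terminal position:     {ws['terminal_position_ticks'] / 64:.1f} rotations")

# for progressive ratio, give the mouse within-session fatigue so responding
# wanes as costs climb, as real animals do
import dataclasses

tiring = dataclasses.replace(agent, satiation_halflife_s=120.0)
cfg = lw.default_config("operant_pr", seed=7, pr_kind="semilog")
log, summary = lw.run_operant_pr(cfg, tiring)
print("progressive ratio (semilog costs 0.25, 0.5, 0.81, ...):")
print(f"  reinforcers earned:    {summary.n_reinforcers}")
print(f"  breakpoint:            {summary.breakpoint} wheel turns")
print(f"  session ended at:      {summary.session_end_ms / 60000:.1f} min")
# The breakpoint — the cost of the last ratio the animal completed before
# 15 min elapsed without a reward — is the session's motivation index.
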