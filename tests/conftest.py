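import numpy as np
import pytest

import lickwheel as lw

# hand-written five-trial brief-access log; every metric on it is computed by
# hand in the tests that use it
FIXTURE_LOG_TEXT = """\
# session_id=fixture5
# task_kind=multispout
# config_digest=00000000
# seed=0
# schema_version=1
# duration_ms=35000
# access_ms=3000
# active_direction=1
# ticks_per_rotation=64
# n_trials=5
# spout_map=0:0,1:1,2:2,3:3,4:4
time_ms,code,value
0,session_start,0
0,trial_start,0
0,spout_extend_cmd,0
250,lick,0
250,solenoid_open,0
400,lick,0
400,solenoid_open,0
550,lick,0
550,solenoid_open,0
3000,spout_retract_cmd,0
3000,trial_end,0
8000,trial_start,1
8000,spout_extend_cmd,1
11000,spout_retract_cmd,1
11000,trial_end,1
16000,trial_start,2
16000,spout_extend_cmd,2
16100,lick,2
16100,solenoid_open,2
16250,lick,2
16250,solenoid_open,2
16400,lick,2
16400,solenoid_open,2
17800,lick,2
17800,solenoid_open,2
17950,lick,2
17950,solenoid_open,2
19000,spout_retract_cmd,2
19000,trial_end,2
24000,trial_start,3
24000,spout_extend_cmd,3
26900,lick,3
26900,solenoid_open,3
27000,spout_retract_cmd,3
27000,trial_end,3
32000,trial_start,4
32000,spout_extend_cmd,4
32000,lick,4
32000,solenoid_open,4
32140,lick,4
32140,solenoid_open,4
35000,spout_retract_cmd,4
35000,trial_end,4
35000,session_end,0
"""


@pytest.fixture(scope="session")
def fixture_log(tmp_path_factory):
    path = tmp_path_factory.mktemp("fixture") / "fixture5.csv"
    path.write_text(FIXTURE_LOG_TEXT)
    return lw.read_log(path)


@pytest.fixture(scope="session")
def multispout_log():
    """One full 100-trial brief-access session with the concentration tracker."""
    cfg = lw.default_config("multispout", seed=42)
    return lw.run_session(cfg, lw.preset("concentration_tracker"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
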