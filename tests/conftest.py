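import numpy as np
import pytest
from hypothesis import settings

from tunatag import SimScenario, simulate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """Two low-rate fish (2 days) plus one high-rate fish (3 h), with table."""
    out = tmp_path_factory.mktemp("cohort")
    scns = [
        SimScenario(fish_id="LOW001", duration_days=2.0, accel_fs=0.2,
                    subdued_days=1, fight_time=15.0, rng_seed=101),
        SimScenario(fish_id="LOW002", duration_days=2.0, accel_fs=0.2,
                    subdued_days=1, fight_time=28.0, tow_time=np.nan,
                    rng_seed=102),
        SimScenario(fish_id="HI0001", duration_days=0.125, accel_fs=20.0,
                    fight_time=10.0, burst_multiplier=1.0,
                    dsf_burst_multiplier=1.0, rng_seed=103),
    ]
    simulate_cohort(scns, out)
    return out
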