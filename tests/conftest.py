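import numpy as np
import pytest

from sclccea.config import load_config
from sclccea.km_ipd import DAYS_PER_MONTH
from sclccea.pipeline import PipelineState
from sclccea.synthetic_trial import digitize, simulate_endpoint


@pytest.fixture(scope="session")
def default_config():
    return load_config()


@pytest.fixture(scope="session")
def fast_state(default_config):
    """Full pipeline on the ETER701-like synthetic trial with a reduced
    (fast) survival-family list; shared across acceptance-style tests."""
    cfg = load_config(overrides={"survival": {"families": ["weibull", "loglogistic"]}})
    return PipelineState.from_synthetic(cfg, seed=1)


@pytest.fixture(scope="session")
def exp_arm_200():
    """200-patient exponential arm (median 12 months), administrative
    censoring at 30 months, digitized on a daily grid with a quarterly
    risk table — the reconstruction round-trip fixture."""
    rate = np.log(2.0) / (12.0 * DAYS_PER_MONTH)
    ipd = simulate_endpoint("exponential", [rate], 200, seed=7,
                            max_followup_days=30.0 * DAYS_PER_MONTH)
    tmax = float(ipd.times_days.max())
    grid = np.arange(0.0, tmax + 1.0, 1.0)
    risk_times = np.arange(0.0, tmax + 1.0, 3.0 * DAYS_PER_MONTH)
    dig = digitize(ipd, grid, risk_times, noise=0.0)
    return ipd, dig
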