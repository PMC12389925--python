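import numpy as np
import pytest

from eegdenoise.pipeline import FrameworkConfig
from eegdenoise.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """Reduced-scale framework config (256-sample windows at 256 Hz)."""
    return FrameworkConfig(
        rtwl_ms=1000.0,
        sr_hz=256.0,
        wavelet="db4",
        if_subsample=128,
        if_trees=50,
        buffer_windows=8,
        anomaly_threshold=0.55,
        expansion_step=0,
        seed=0,
    )


@pytest.fixture
def small_sim_cfg():
    """Reduced-scale synthetic stream matching ``small_cfg`` (bursts at 60-100 Hz)."""
    return SimConfig(
        n_channels=2,
        duration_s=40.0,
        sr_hz=256.0,
        burst_band=(30.0, 100.0),
        emphasis_band=(60.0, 100.0),
        seed=0,
    )
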