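import numpy as np
import pytest

from spindletools import SynthConfig, generate_recording


def tone(freq, dur_s=10.0, rate=1000.0, amp=1.0, phase=0.0):
    t = np.arange(int(round(dur_s * rate))) / rate
    return amp * np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture(scope="session")
def rec4():
    """4-minute default-condition recording with ground truth."""
    cfg = SynthConfig(seed=11, duration_min=4)
    signals, gt = generate_recording(cfg)
    return cfg, signals, gt


@pytest.fixture(scope="session")
def rec_dense():
    """Recording with dense spindles for coupling analyses."""
    cfg = SynthConfig(seed=5, duration_min=15, spindle_rate_per_min=9.0,
                      pre_rem_boost=1.0)
    signals, gt = generate_recording(cfg)
    return cfg, signals, gt
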