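import numpy as np
import pytest

from pulsetrack import PipelineConfig, SignalChannel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ring_config():
    """Pipeline configuration at the smart-ring common rate (39 Hz)."""
    return PipelineConfig(target_rate_hz=39.0)


@pytest.fixture
def uniform_channel():
    def make(values, rate, label="ppg", t0=0.0):
        return SignalChannel.from_uniform(np.asarray(values, float), rate, t0=t0, label=label)

    return make
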