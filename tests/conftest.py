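import numpy as np
import pytest

from cmapkit import NoiseSpec, RecordingMeta, SimConfig


@pytest.fixture
def meta():
    return RecordingMeta()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quiet_config():
    """Noise-free, jitter-free simulator configuration."""
    return SimConfig(
        noise=NoiseSpec(white_sd=0.0, line_amplitude=0.0),
        latency_jitter_sd=0.0,
    )
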