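import numpy as np
import pytest

from eventfall.core import TriaxialStream
from eventfall.event_segmenter import EventSegmenterConfig
from eventfall.synth import GeneratorConfig, _sequence_rng


@pytest.fixture
def stream_from_avm():
    """Factory: a stream whose z axis carries a given avm series exactly."""

    def make(values, fs=100.0):
        values = np.asarray(values, dtype=float)
        data = np.zeros((len(values), 3))
        data[:, 2] = values
        return TriaxialStream(fs, data)

    return make


@pytest.fixture
def default_segmenter_config():
    return EventSegmenterConfig()


@pytest.fixture
def generator_config():
    return GeneratorConfig(seed=12345)


@pytest.fixture
def sequence_rng():
    """Factory for a per-(subject, sequence) generator substream."""

    def make(config, subject_idx, seq_idx):
        return _sequence_rng(config, subject_idx, seq_idx)

    return make
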