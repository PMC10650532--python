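import numpy as np
import pytest

from eegcrypt import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return GeneratorConfig()


@pytest.fixture
def short_config():
    """1-second segments: cheap to generate and transform."""
    return GeneratorConfig(segment_length_s=1.0, n_channels=2, seed=42)
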