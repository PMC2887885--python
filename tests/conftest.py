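import numpy as np
import pytest

import cuffeng as ce


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def proprio_config():
    """Single-stimulus generator config at the strongest in-vivo SNR column."""
    return ce.GeneratorConfig(classes=("proprio",), seed=11).with_snr(proprio=3.823)


@pytest.fixture(scope="session")
def proprio_recording(proprio_config):
    return ce.generate_recording(proprio_config)


@pytest.fixture(scope="session")
def filtered_proprio(proprio_recording):
    return ce.bandpass_filter(proprio_recording)
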