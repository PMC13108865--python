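import numpy as np
import pytest

from wormcal import (
    SimConfig,
    build_kymograph,
    detect_peaks,
    extract_trace,
    generate_recording,
)


@pytest.fixture(scope="session")
def regular_config():
    """Two regular posterior-initiated waves in a 2-minute recording."""
    return SimConfig(duration_s=120.0, seed=7)


@pytest.fixture(scope="session")
def regular_recording(regular_config):
    return generate_recording(regular_config)


@pytest.fixture(scope="session")
def regular_trace(regular_recording):
    rec, _ = regular_recording
    return extract_trace(rec)


@pytest.fixture(scope="session")
def regular_kymograph(regular_recording, regular_trace):
    rec, _ = regular_recording
    _, masks = regular_trace
    return build_kymograph(rec, masks)


@pytest.fixture(scope="session")
def regular_peaks(regular_trace):
    trace, _ = regular_trace
    return detect_peaks(trace)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
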