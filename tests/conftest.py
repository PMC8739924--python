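import numpy as np
import pytest

from pulsewave.synthetic_data import CycleParams, generate_cycle, generate_recording

FS = 720.0


@pytest.fixture(scope="session")
def default_params() -> CycleParams:
    return CycleParams()


@pytest.fixture(scope="session")
def clean_cycle(default_params):
    """One zero-noise cycle at the study sampling rate, with its truth."""
    return generate_cycle(default_params, FS)


@pytest.fixture(scope="session")
def clean_recording(default_params):
    """A 12-s zero-noise recording with period jitter, with its truth."""
    return generate_recording(default_params, 12.0, FS, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
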