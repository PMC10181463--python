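import numpy as np
import pytest

from eegcascade.io_recordings import Recording
from eegcascade.synthetic import SimulationConfig, simulate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """A 2-channel, 1 s recording with a mid-file trigger pulse."""
    n = 512
    trigger = np.zeros(n)
    trigger[200:300] = 5.0
    return Recording(
        signals=rng.normal(0.0, 20.0, size=(2, n)),
        fs=512.0,
        channel_labels=["C3", "C4"],
        trigger=trigger,
        subject_id="S42",
        recording_id="R1",
    )


@pytest.fixture(scope="session")
def default_recording():
    """One full synthetic session under the default 16-channel montage."""
    return simulate_recording(SimulationConfig(n_subjects=1, n_recordings=1,
                                               seed=7), 0, 0)
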