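import numpy as np
import pytest

from measort import detect as det
from measort import simulate as sim


@pytest.fixture(scope="session")
def short_signal():
    """A 12-s, 2-unit, SNR-4 signal with ground truth."""
    spec = sim.SimulationSpec(n_units=2, snr_target=4.0, duration_s=12.0,
                              seed=3)
    return sim.simulate_signal(spec)


@pytest.fixture(scope="session")
def detected(short_signal):
    """Filtered trace + aligned spike waveforms of the short signal."""
    trace, truth = short_signal
    filt = det.bandpass(trace)
    waves = det.detect_and_extract(filt)
    return filt, waves, truth


@pytest.fixture(scope="session")
def waveform_matrix(detected):
    _, waves, _ = detected
    return np.array([w.samples for w in waves])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
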