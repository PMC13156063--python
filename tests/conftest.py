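import numpy as np
import pytest

from neurofuse.io_preprocess import DEFAULT_CHANNELS, Recording
from neurofuse.synthetic_data import OscillationSpec, SubjectSpec, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_recording(rng):
    """8-channel white-noise recording, 60 s at 250 Hz."""
    return Recording(
        rng.standard_normal((8, 15000)), fs=250.0, labels=list(DEFAULT_CHANNELS)
    )


@pytest.fixture
def alpha_recording():
    """Recording with a single planted 10 Hz (2 Hz FWHM) rhythm on all channels."""
    spec = SubjectSpec(
        oscillations=[
            OscillationSpec(10.0, 2.0, {c: 2.0 for c in DEFAULT_CHANNELS})
        ],
        duration=60.0,
        fs=250.0,
        seed=7,
    )
    rec, _ = generate_subject(spec)
    return rec


def sine_recording(freq: float, fs: float = 250.0, dur: float = 10.0, channels=2):
    t = np.arange(int(dur * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (channels, 1))
    return Recording(data, fs=fs, labels=[f"ch{i}" for i in range(channels)])
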