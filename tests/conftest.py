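import numpy as np
import pytest

from vibrotrace.eeg_core import EEGRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, fs=500.0, labels=None, **kw):
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = tuple(f"ch{i:02d}" for i in range(data.shape[0]))
    return EEGRecording(data=data, fs=fs, channel_labels=labels, **kw)


@pytest.fixture
def toy_recording():
    return make_recording([[1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 30.0, 40.0]])
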