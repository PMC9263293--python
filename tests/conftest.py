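import numpy as np
import pytest

from plvnet.preprocess import DEFAULT_MONTAGE, EEGRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tone_recording(
    freq_hz: float = 10.0,
    fs: float = 250.0,
    duration_s: float = 10.0,
    n_channels: int = 2,
    subject_id: str = "S1",
) -> EEGRecording:
    t = np.arange(int(duration_s * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq_hz * t), (n_channels, 1))
    return EEGRecording(
        data=data,
        sampling_rate_hz=fs,
        channel_labels=DEFAULT_MONTAGE.channels[:n_channels],
        subject_id=subject_id,
    )


@pytest.fixture
def tone_recording():
    return make_tone_recording()


def random_symmetric_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    m = rng.random((n, n))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return m
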