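import numpy as np
import pytest

from emdwave.io_signals import MONTAGE, InterestLabel
from emdwave.preprocess import Segment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_segment8(rng):
    """8-channel, 8 s, 250 Hz random segment for fast feature tests."""
    return Segment(
        data=rng.standard_normal((8, 2000)) * 20.0,
        fs=250.0,
        channel_names=MONTAGE,
        subject_id="s0",
        label=InterestLabel("high", 85.0),
    )


def make_tone_segment(freq_hz, fs=250.0, duration_s=8.0, channels=MONTAGE,
                      amplitude=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    tone = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return Segment(
        data=np.tile(tone, (len(channels), 1)),
        fs=fs,
        channel_names=tuple(channels),
        label=InterestLabel("high", 85.0),
    )
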