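import numpy as np
import pytest

from neocoupling.signal_io import ChannelMeta, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(samples, fs=1000.0, area="OB"):
    """Wrap a [k x n] array as a single-probe Recording."""
    k = samples.shape[0]
    channels = [ChannelMeta(area=area, depth_um=400.0 + 50.0 * i, index=i) for i in range(k)]
    return Recording(samples=samples, fs=fs, channels=channels)


@pytest.fixture
def tone():
    """10 s of a unit 3 Hz cosine at 1 kHz."""
    fs = 1000.0
    t = np.arange(0, 10, 1 / fs)
    return np.cos(2 * np.pi * 3 * t), fs
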