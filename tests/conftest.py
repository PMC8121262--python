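import numpy as np
import pytest

from gednet import make_channel_meta, synthetic
from gednet.recording import Recording


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_truth():
    """Single 8-Hz network over 3 regions, one coupled multiunit."""
    return synthetic.generate_ground_truth(
        1, (8.0, 8.0), regions=("PFC", "PAR", "HIP"),
        channels_per_region=(4, 4, 4), seed=11)


@pytest.fixture(scope="session")
def small_recording(small_truth):
    return synthetic.generate_recording(small_truth, duration=40.0, fs=500.0,
                                        snr=1.5, seed=21)


@pytest.fixture
def noise_recording():
    """Source-free 1/f recording, 12 channels in 3 regions."""
    rng = np.random.default_rng(7)
    data = synthetic.one_over_f_noise(30_000, 500.0, 1.0, rng, size=12)
    meta = make_channel_meta([f"ch{i}" for i in range(12)],
                             ["LFP"] * 12,
                             ["PFC"] * 4 + ["PAR"] * 4 + ["HIP"] * 4)
    return Recording(data, 500.0, meta)
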