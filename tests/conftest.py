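import numpy as np
import pytest

from taugraph.preprocess import EpochedData, Recording
from taugraph.synthetic import CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_config():
    """Reduced-scale cohort config used throughout the simulation tests."""
    return CohortConfig(seed=0, n_channels=16, duration_s=100, fs=128)


def make_sine_recording(freq: float, fs: float = 256.0, duration: float = 40.0,
                        n_channels: int = 2, noise: float = 0.0,
                        seed: int = 0) -> Recording:
    t = np.arange(int(duration * fs)) / fs
    x = np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))
    if noise > 0:
        x = x + noise * np.random.default_rng(seed).standard_normal(x.shape)
    labels = [f"ch{i}" for i in range(n_channels)]
    return Recording(samples=x, fs=fs, channel_labels=labels)


def make_epochs(data: np.ndarray, fs: float, epoch_s: float) -> EpochedData:
    labels = [f"ch{i}" for i in range(data.shape[1])]
    return EpochedData(data=data, fs=fs, channel_labels=labels,
                       epoch_length_s=epoch_s)
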