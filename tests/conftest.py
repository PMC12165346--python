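import numpy as np
import pytest

from wavemaml.models import ArchitectureConfig, ResNetConfig, TransformerConfig
from wavemaml.recording import EEGRecording


@pytest.fixture(scope="session")
def micro_arch() -> ArchitectureConfig:
    """Smallest viable architecture (8x8 input) for fast gradient tests."""
    return ArchitectureConfig(
        input_size=(8, 8, 1),
        conv_channels=(2, 2),
        dropout_rate=0.0,
        transformer=TransformerConfig(n_heads=1, model_dim=4, ffn_dim=8, token_grid=2),
        resnet=ResNetConfig(width=2),
    )


@pytest.fixture(scope="session")
def desk_arch32() -> ArchitectureConfig:
    return ArchitectureConfig.desk_scale((32, 32, 1))


def tone_recording(freq: float, fs: float = 250.0, seconds: float = 4.0,
                   channels: tuple[str, ...] = ("F4",)) -> EEGRecording:
    t = np.arange(int(seconds * fs)) / fs
    sig = np.tile(np.sin(2 * np.pi * freq * t), (len(channels), 1))
    return EEGRecording(signal=sig, fs=fs, channel_names=channels)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
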