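"""Shared fixtures: small synthetic recordings and epoch sets."""

import numpy as np
import pytest

from eegscreen.config import PipelineConfig
from eegscreen.montage import CHANNELS
from eegscreen.types import EpochSet, Recording

FS = 256.0


def make_recording(data: np.ndarray, participant_id: str = "sub-test",
                   channels=CHANNELS, fs: float = FS) -> Recording:
    return Recording(participant_id, channels, fs, data)


def white_epochs(n_epochs: int, n_channels: int, n_samples: int = 2560,
                 seed: int = 0, channels=None) -> EpochSet:
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_epochs, n_channels, n_samples))
    chans = channels or CHANNELS[:n_channels]
    return EpochSet("sub-test", data, np.arange(n_epochs) * 8.0, FS, chans)


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
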