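import numpy as np
import pytest

from pcgmel.acquisition_sim import HeartSoundParams, synth_clean_pcg
from pcgmel.features import StftConfig, build_mel_filterbank
from pcgmel.io_preprocess import AudioRecording, PreprocessConfig

FS = 2000.0


@pytest.fixture(scope="session")
def pre_cfg() -> PreprocessConfig:
    return PreprocessConfig()


@pytest.fixture(scope="session")
def stft_cfg() -> StftConfig:
    return StftConfig()


@pytest.fixture(scope="session")
def filterbank():
    return build_mel_filterbank()


@pytest.fixture(scope="session")
def clean_pcg() -> AudioRecording:
    """A 10 s normal heart sound at 70 bpm, deterministic."""
    return synth_clean_pcg(HeartSoundParams(heart_rate_bpm=70.0), 10.0, FS, seed=7)


@pytest.fixture(scope="session")
def murmur_pcg() -> AudioRecording:
    """A 10 s abnormal (murmur) heart sound: broadband systolic bursts."""
    return synth_clean_pcg(
        HeartSoundParams(heart_rate_bpm=70.0, murmur_present=True),
        10.0, FS, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
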