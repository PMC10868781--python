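import numpy as np
import pytest

from echostream.containers import AuditorySpectrogram
from echostream.synth import SynthConfig, speech_like_audio, speech_like_envelope


@pytest.fixture(scope="session")
def speech_audio_60s():
    """One minute of seeded speech-like audio, shared across tests."""
    return speech_like_audio(SynthConfig(duration_s=60.0, seed=11))


@pytest.fixture(scope="session")
def speech_env_600s():
    """Ten minutes of seeded speech-like envelope at 100 Hz."""
    return speech_like_envelope(SynthConfig(duration_s=600.0, seed=7))


@pytest.fixture()
def small_spectrogram():
    """5-s, 16-channel random nonnegative spectrogram at 200 Hz."""
    rng = np.random.default_rng(42)
    vals = rng.random((16, 1000))
    return AuditorySpectrogram(vals, np.geomspace(200.0, 4000.0, 16), 200.0)
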