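import numpy as np
import pytest

from broilervoc.audio import AudioClip
from broilervoc.netspec import ArchitectureSpec, LayerSpec, table1


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone():
    """Factory for pure-tone clips."""

    def _tone(freq_hz, duration_s, rate=16000, amplitude=0.5, phase=0.0):
        t = np.arange(int(round(duration_s * rate))) / rate
        return AudioClip(amplitude * np.sin(2 * np.pi * freq_hz * t + phase), rate)

    return _tone


@pytest.fixture
def chirp():
    """Factory for linear-chirp clips (f0 -> f1 over the duration)."""

    def _chirp(f0, f1, duration_s, rate=16000, amplitude=0.5):
        t = np.arange(int(round(duration_s * rate))) / rate
        f = f0 + (f1 - f0) * t / duration_s
        phase = 2 * np.pi * np.cumsum(f) / rate
        return AudioClip(amplitude * np.sin(phase), rate)

    return _chirp


@pytest.fixture(scope="session")
def table1_spec():
    return table1()


@pytest.fixture(scope="session")
def tiny_spec():
    """A fast 3-layer stand-in architecture for training-loop tests.

    Receptive field 5 frames, stride 2, frequency collapses 7 -> 1.
    """
    return ArchitectureSpec(
        layers=(
            LayerSpec("conv2d", 4, (3, 3), (1, 1)),
            LayerSpec("conv2d", 8, (3, 5), (2, 3)),
            LayerSpec("conv1d", 6, (1, 1), (1, 1), activation="head",
                      batch_norm=False),
        ),
        input_shape=(5, 7),
    )
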