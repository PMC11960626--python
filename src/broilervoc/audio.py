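"""Mono audio container and basic waveform I/O.

All audio in this package travels as :class:`AudioClip`: a 1-D float
waveform in [-1, 1] plus its sample rate. Field recordings are nominally
48 kHz; the detector front end resamples to 16 kHz before analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = ["AudioClip", "read_wav", "write_wav", "resample"]


@dataclass
class AudioClip:
    """A mono audio signal.

    Parameters
    ----------
    samples
        1-D float array of samples, magnitudes expected within [-1, 1]
        after normalization.
    rate
        Sampling rate in Hz; must be positive.
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).reshape(-1)
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Clip duration in seconds."""
        return self.samples.size / self.rate

    def rms(self) -> float:
        if self.samples.size == 0:
            return 0.0
        return float(np.sqrt(np.mean(self.samples**2)))

    def normalized(self, peak: float = 1.0) -> "AudioClip":
        """Scale so the absolute peak equals ``peak`` (no-op on silence)."""
        m = np.max(np.abs(self.samples)) if self.samples.size else 0.0
        if m == 0:
            return AudioClip(self.samples.copy(), self.rate)
        return AudioClip(self.samples * (peak / m), self.rate)


def read_wav(path) -> AudioClip:
    """Read a PCM-16 or float32 WAV file as a mono :class:`AudioClip`.

    Multi-channel files are mixed down by averaging channels.
    """
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        data = data.astype(np.float64) / max(abs(info.min), info.max)
    else:
        data = data.astype(np.float64)
    return AudioClip(data, int(rate))


def write_wav(path, clip: AudioClip, subtype: str = "float32") -> None:
    """Write a clip to WAV (``subtype`` 'float32' or 'pcm16')."""
    if subtype == "float32":
        wavfile.write(path, clip.rate, clip.samples.astype(np.float32))
    elif subtype == "pcm16":
        x = np.clip(clip.samples, -1.0, 1.0)
        wavfile.write(path, clip.rate, np.round(x * 32767).astype(np.int16))
    else:
        raise ValueError(f"unknown WAV subtype {subtype!r}")


def resample(clip: AudioClip, target_rate: int) -> AudioClip:
    """Band-limited polyphase resampling to ``target_rate`` Hz.

    Duration is preserved to within one sample period. A clip already at
    the target rate is returned unchanged (same object); an empty clip
    resamples to an empty clip.
    """
    if target_rate <= 0:
        raise ValueError(f"target rate must be positive, got {target_rate}")
    if clip.rate == target_rate:
        return clip
    if len(clip) == 0:
        return AudioClip(np.empty(0), target_rate)
    g = math.gcd(int(target_rate), int(clip.rate))
    up, down = target_rate // g, clip.rate // g
    out = resample_poly(clip.samples, up, down)
    return AudioClip(out, target_rate)
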