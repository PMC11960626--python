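"""Log-mel spectrogram front end of the vocalization detector.

The detector consumes a 64-band log-mel spectrogram computed from 16 kHz
audio with a 512-point STFT (Hann window, 10 ms hop) and mel filters
spanning 50 Hz - 8 kHz. Power is converted to decibels relative to the
spectrogram maximum, floored at -80 dB, and mapped linearly onto [-1, 1],
so silence sits at -1 and the per-recording peak at +1.

Framing convention: frame ``k`` is centred on sample ``k * hop`` with
reflection padding at the edges, for ``k = 0 .. floor(N / hop) - 1``; a
1.94 s clip at 16 kHz therefore yields exactly 194 frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import AudioClip

__all__ = [
    "FrontendConfig",
    "LogMelSpectrogram",
    "mel_filterbank",
    "compute_logmel",
]


@dataclass
class FrontendConfig:
    sample_rate: int = 16000
    n_fft: int = 512
    hop: int = 160
    n_mels: int = 64
    fmin: float = 50.0
    fmax: float = 8000.0
    db_floor: float = -80.0


DEFAULT_FRONTEND = FrontendConfig()


@dataclass
class LogMelSpectrogram:
    """frames x n_mels matrix of scaled log-mel values in [-1, 1]."""

    values: np.ndarray           # (frames, n_mels)
    hop_seconds: float           # frame spacing, 0.010 s by default
    band_centers: np.ndarray     # mel band centre frequencies in Hz

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, n_fft: int, rate: int, fmin: float, fmax: float
) -> tuple[np.ndarray, np.ndarray]:
    """Triangular, area-normalized mel filterbank.

    Returns ``(weights, centers)`` where ``weights`` has shape
    ``(n_mels, n_fft // 2 + 1)`` and ``centers`` holds the filter centre
    frequencies in Hz.
    """
    edges = _mel_to_hz(np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2))
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    weights = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (fft_freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - mid, 1e-12)
        tri = np.maximum(0.0, np.minimum(up, down))
        # area normalization: unit integral over Hz
        area = np.trapezoid(tri, fft_freqs)
        if area > 0:
            tri /= area
        weights[i] = tri
    return weights, edges[1:-1]


def compute_logmel(
    clip: AudioClip, config: FrontendConfig = DEFAULT_FRONTEND
) -> LogMelSpectrogram:
    """Compute the scaled log-mel spectrogram of a 16 kHz clip.

    Raises ``ValueError`` if the clip is not at ``config.sample_rate`` or
    is shorter than one hop.
    """
    if clip.rate != config.sample_rate:
        raise ValueError(
            f"clip rate {clip.rate} Hz != front-end rate {config.sample_rate} Hz; "
            "resample first"
        )
    n = len(clip)
    hop, n_fft = config.hop, config.n_fft
    n_frames = n // hop
    if n_frames < 1:
        raise ValueError(f"clip of {n} samples is shorter than one hop ({hop})")

    half = n_fft // 2
    x = clip.samples
    if n > half:
        padded = np.pad(x, half, mode="reflect")
    else:  # too short for reflection; zero-pad (degenerate, sub-32 ms input)
        padded = np.pad(x, half, mode="constant")
    window = np.hanning(n_fft + 1)[:n_fft]

    idx = np.arange(n_frames)[:, None] * hop + np.arange(n_fft)[None, :]
    frames = padded[idx] * window
    spec = np.abs(np.fft.rfft(frames, axis=1)) ** 2

    weights, centers = mel_filterbank(
        config.n_mels, n_fft, config.sample_rate, config.fmin, config.fmax
    )
    mel = spec @ weights.T  # (frames, n_mels)

    ref = mel.max()
    if ref <= 0:
        values = np.full_like(mel, -1.0)
    else:
        db = 10.0 * np.log10(np.maximum(mel / ref, 10.0 ** (config.db_floor / 10.0)))
        values = 1.0 + 2.0 * db / (-config.db_floor)  # [-80, 0] -> [-1, 1]
    return LogMelSpectrogram(
        values=values, hop_seconds=hop / config.sample_rate, band_centers=centers
    )
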