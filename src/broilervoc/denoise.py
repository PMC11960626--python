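"""Spectral-gating noise suppression.

Broiler-house recordings carry ventilation, feeder and human noise. The
denoiser follows the spectral-gating scheme: estimate a per-band noise
threshold from a smoothed noise statistic, build a soft time-frequency
mask that attenuates bins below threshold, smooth the mask over time and
frequency, and apply it to the STFT before inverting back to a waveform.

Two modes are supported:

* stationary — noise statistics come from a separate noise-only clip;
* non-stationary (default) — statistics are estimated from the clip
  itself with a rolling window, tracking slowly varying backgrounds.

The output always has the same length and sample rate as the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter, uniform_filter1d
from scipy.signal import istft, stft

from .audio import AudioClip

__all__ = ["DenoiseConfig", "denoise_spectral_gating"]

_EPS = 1e-12


@dataclass
class DenoiseConfig:
    n_fft: int = 512
    hop: int = 128
    n_std: float = 1.5            # threshold = smoothed mean + n_std * SD (dB)
    sigmoid_width_db: float = 3.0  # softness of the gate around the threshold
    smooth_bands: int = 3          # mask smoothing extent over frequency
    smooth_frames: int = 5         # mask smoothing extent over time
    rolling_seconds: float = 1.0   # statistics window in non-stationary mode


DEFAULT_DENOISE = DenoiseConfig()


def denoise_spectral_gating(
    clip: AudioClip,
    noise_clip: AudioClip | None = None,
    config: DenoiseConfig = DEFAULT_DENOISE,
) -> AudioClip:
    """Suppress background noise in ``clip`` by spectral gating.

    If ``noise_clip`` is given its spectrum defines the (stationary) noise
    statistics; otherwise the clip's own rolling statistics are used.
    Clips shorter than one STFT window are returned unchanged with a
    warning.
    """
    n = len(clip)
    if n < config.n_fft:
        warnings.warn(
            f"clip of {n} samples is shorter than one STFT window "
            f"({config.n_fft}); returned unchanged",
            stacklevel=2,
        )
        return AudioClip(clip.samples.copy(), clip.rate)

    noverlap = config.n_fft - config.hop
    _, _, S = stft(
        clip.samples, fs=clip.rate, nperseg=config.n_fft, noverlap=noverlap
    )
    db = 20.0 * np.log10(np.abs(S) + _EPS)  # (bands, frames)

    if noise_clip is not None and len(noise_clip) >= config.n_fft:
        _, _, Sn = stft(
            noise_clip.samples, fs=clip.rate, nperseg=config.n_fft, noverlap=noverlap
        )
        ndb = 20.0 * np.log10(np.abs(Sn) + _EPS)
        thresh = ndb.mean(axis=1) + config.n_std * ndb.std(axis=1)
        thresh = thresh[:, None]
    else:
        width = max(3, int(round(config.rolling_seconds * clip.rate / config.hop)))
        width = min(width, db.shape[1])
        mean = uniform_filter1d(db, size=width, axis=1, mode="nearest")
        sq = uniform_filter1d(db**2, size=width, axis=1, mode="nearest")
        sd = np.sqrt(np.maximum(sq - mean**2, 0.0))
        thresh = mean + config.n_std * sd

    mask = 1.0 / (1.0 + np.exp(-(db - thresh) / config.sigmoid_width_db))
    mask = uniform_filter(
        mask, size=(config.smooth_bands, config.smooth_frames), mode="nearest"
    )

    _, out = istft(S * mask, fs=clip.rate, nperseg=config.n_fft, noverlap=noverlap)
    if out.size >= n:
        out = out[:n]
    else:
        out = np.pad(out, (0, n - out.size))
    return AudioClip(out, clip.rate)
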