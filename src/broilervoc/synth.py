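"""Synthetic broiler calls and background audio with known ground truth.

No public recording database of broiler vocalizations exists, so every
other module in this package is exercised against synthetic audio whose
statistics follow the published per-class, per-week acoustics of the
four vocalization types (duration, peak power, fundamental frequency,
and f0 trend, each as mean +/- SD):

* distress calls — loud, steeply descending pitch, produced in
  repetitive bouts of 2-5 calls;
* pleasure notes — quiet, ascending pitch (absent after week 3, as in
  the source data);
* short peeps — quiet, short, descending;
* warbles — longest calls, bow-shaped (half-sine) pitch excursion.

Feature values are drawn from truncated normal distributions (mean
+/- 2.5 SD, further clipped to physical bounds), converted to a
harmonic waveform (fundamental + 2 harmonics with -8 dB/harmonic
rolloff) with an attack-decay amplitude envelope, and scaled so that
the measured 10 ms peak RMS matches the drawn peak power in dB re full
scale. Two non-vocalization classes complete the training taxonomy:
"other" (an inharmonic noise-burst sound) and "background"
(vocalization-free shaped noise and/or 50 Hz-harmonic hum emulating
ventilation and mains interference).

Everything is seeded and returns ground truth (onsets, f0 trajectory,
drawn feature values), so detector and feature-extraction tests have
an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter
from scipy.stats import truncnorm

from .audio import AudioClip
from .training import CLASSES_5, LabeledSample

__all__ = [
    "TABLE3_STATS",
    "CallStats",
    "SynthCallParams",
    "CallTruth",
    "synth_call",
    "synth_background",
    "make_dataset",
    "write_dataset",
    "week_age_range",
]

_EPS = 1e-12


@dataclass(frozen=True)
class CallStats:
    """Mean +/- SD of the four call features for one (class, week) cell."""

    duration_s: tuple[float, float]
    peak_power_db: tuple[float, float]
    f0_hz: tuple[float, float]
    trend_hz_per_10ms: tuple[float, float]


def _cs(d, ds, p, ps, f, fs, t, ts):
    return CallStats((d, ds), (p, ps), (f, fs), (t, ts))


# Per-class, per-week call acoustics (weeks 1-5; pleasure notes are not
# observed in weeks 4-5).
TABLE3_STATS: dict[str, dict[int, CallStats]] = {
    "distress": {
        1: _cs(0.19, 0.08, -43.4, 7.5, 2994, 398, -48.9, 28.0),
        2: _cs(0.20, 0.09, -51.8, 7.1, 3005, 189, -66.3, 25.3),
        3: _cs(0.18, 0.08, -46.3, 7.6, 2786, 741, -45.3, 37.8),
        4: _cs(0.22, 0.11, -48.9, 8.8, 2238, 748, -20.6, 31.4),
        5: _cs(0.20, 0.10, -45.5, 8.6, 1617, 856, -9.1, 31.7),
    },
    "pleasure": {
        1: _cs(0.21, 0.11, -62.5, 2.8, 2945, 388, 30.6, 27.1),
        2: _cs(0.22, 0.11, -61.6, 3.7, 2687, 272, 17.5, 26.3),
        3: _cs(0.21, 0.10, -58.2, 3.5, 2483, 437, 8.4, 25.0),
    },
    "short_peep": {
        1: _cs(0.19, 0.07, -58.5, 5.2, 2839, 441, -55.7, 39.3),
        2: _cs(0.27, 0.12, -60.4, 3.7, 2991, 399, -44.9, 32.3),
        3: _cs(0.23, 0.11, -57.7, 6.0, 2651, 698, -42.7, 36.5),
        4: _cs(0.22, 0.14, -59.0, 4.4, 2478, 579, -28.4, 34.3),
        5: _cs(0.20, 0.12, -55.4, 5.8, 2002, 792, -27.5, 29.9),
    },
    "warble": {
        1: _cs(0.30, 0.15, -63.6, 2.3, 3110, 302, 27.8, 24.1),
        2: _cs(0.35, 0.13, -60.5, 4.0, 2854, 639, -5.7, 23.6),
        3: _cs(0.30, 0.19, -60.5, 4.0, 2771, 736, -19.0, 37.1),
        4: _cs(0.29, 0.17, -59.9, 4.1, 2481, 464, -9.3, 24.5),
        5: _cs(0.37, 0.23, -55.8, 3.8, 1197, 1382, -6.0, 9.9),
    },
}

# Invented statistics for the "other sounds" class (no published
# acoustics exist): a noise-burst sound, constant across weeks.
OTHER_STATS = _cs(0.35, 0.12, -55.0, 5.0, float("nan"), 0.0, float("nan"), 0.0)

_CONTOURS = {"distress": "linear", "pleasure": "linear",
             "short_peep": "linear", "warble": "bow"}
F0_BOUNDS = (400.0, 6000.0)
DURATION_BOUNDS = (0.05, 2.0)


def week_age_range(week: int) -> tuple[int, int]:
    """Inclusive day-of-life range of a study week (1-36 days)."""
    if not 1 <= week <= 5:
        raise ValueError(f"week must be in 1..5, got {week}")
    return (7 * (week - 1) + 1, 36 if week == 5 else 7 * week)


@dataclass
class SynthCallParams:
    """Generator settings for one (class, week) cell."""

    label: str
    week: int
    stats: CallStats
    contour: str = "linear"            # 'linear' | 'bow'
    n_harmonics: int = 3
    harmonic_rolloff_db: float = 8.0
    bout_range: tuple[int, int] = (1, 1)   # distress: (2, 5)
    bout_gap_s: tuple[float, float] = (0.080, 0.200)
    bow_depth_frac: tuple[float, float] = (0.12, 0.04)  # mean, SD of |A|/f0
    bow_period_s: tuple[float, float] = (0.08, 0.15)    # bow-element length range
    trunc_sigmas: float = 2.5
    sample_rate: int = 16000

    @classmethod
    def from_table(cls, label: str, week: int) -> "SynthCallParams":
        if not 1 <= week <= 5:
            raise ValueError(f"week must be in 1..5, got {week}")
        if label not in TABLE3_STATS:
            raise ValueError(f"no call statistics for class {label!r}")
        if week not in TABLE3_STATS[label]:
            raise ValueError(
                f"{label!r} calls are not observed in week {week}; "
                "no generator parameters exist"
            )
        return cls(
            label=label,
            week=week,
            stats=TABLE3_STATS[label][week],
            contour=_CONTOURS[label],
            bout_range=(2, 5) if label == "distress" else (1, 1),
        )


@dataclass
class CallTruth:
    """Ground truth accompanying a synthesized call element."""

    onset_s: float
    offset_s: float
    f0_times_s: np.ndarray
    f0_hz: np.ndarray
    drawn: dict


def _trunc_draw(rng, mean, sd, lo, hi, sigmas=2.5, size=None):
    """Truncated-normal draw: mean +/- sigmas*SD intersected with [lo, hi]."""
    if sd <= 0:
        return mean if size is None else np.full(size, mean)
    a = max(lo, mean - sigmas * sd)
    b = min(hi, mean + sigmas * sd)
    u = rng.random(size)
    za, zb = (a - mean) / sd, (b - mean) / sd
    return truncnorm.ppf(u, za, zb, loc=mean, scale=sd)


def draw_call_descriptors(params: SynthCallParams, rng) -> dict:
    """Draw the per-call feature values that the waveform will realize."""
    s = params.stats
    d = {
        "duration_s": float(
            _trunc_draw(rng, *s.duration_s, *DURATION_BOUNDS, params.trunc_sigmas)
        ),
        "peak_power_db": float(
            _trunc_draw(rng, *s.peak_power_db, -90.0, -3.0, params.trunc_sigmas)
        ),
        "f0_hz": float(
            _trunc_draw(rng, *s.f0_hz, *F0_BOUNDS, params.trunc_sigmas)
        ),
        "trend_hz_per_10ms": float(
            _trunc_draw(
                rng, *s.trend_hz_per_10ms, -300.0, 300.0, params.trunc_sigmas
            )
        ),
        "bout_n": int(rng.integers(params.bout_range[0], params.bout_range[1] + 1)),
    }
    if params.contour == "bow":
        d["bow_depth_hz"] = float(
            abs(rng.normal(*params.bow_depth_frac)) * d["f0_hz"]
        )
        d["bow_period_s"] = float(rng.uniform(*params.bow_period_s))
    else:
        d["bow_depth_hz"] = 0.0
        d["bow_period_s"] = 0.0
    return d


def _call_waveform(params: SynthCallParams, drawn: dict, rng):
    """Single call element realizing the drawn descriptors."""
    sr = params.sample_rate
    dur = drawn["duration_s"]
    n = max(int(round(dur * sr)), 8)
    t = np.arange(n) / sr
    attack = 0.25 * dur
    t_peak = attack

    slope = drawn["trend_hz_per_10ms"] * 100.0  # Hz per second
    f = drawn["f0_hz"] + slope * (t - t_peak)
    if params.contour == "bow":
        # repetitive bow-shaped elements: arched f0 excursions repeated
        # every bow_period_s across the call
        t_el = max(drawn.get("bow_period_s", 0.0), 0.02)
        arch = np.abs(np.sin(np.pi * t / t_el))
        arch_at_peak = abs(np.sin(np.pi * t_peak / t_el))
        f = f + drawn["bow_depth_hz"] * (arch - arch_at_peak)
    f = np.clip(f, 250.0, 0.45 * sr)

    env = np.where(
        t < attack,
        np.sin(np.pi * t / (2 * max(attack, _EPS))) ** 2,
        np.cos(np.pi * (t - attack) / (2 * max(dur - attack, _EPS))) ** 2,
    )
    phase = 2 * np.pi * np.cumsum(f) / sr
    x = np.zeros(n)
    for h in range(1, params.n_harmonics + 1):
        if h * f.max() >= 0.48 * sr:
            break
        amp = 10.0 ** (-(h - 1) * params.harmonic_rolloff_db / 20.0)
        x += amp * np.sin(h * phase + rng.uniform(0, 2 * np.pi))
    x *= env

    # scale so the measured 10 ms peak RMS equals the drawn peak power
    win = max(1, int(round(0.010 * sr)))
    m = n // win
    rms = np.sqrt(np.mean(x[: m * win].reshape(m, win) ** 2, axis=1))
    peak_rms = rms.max() if m else np.sqrt(np.mean(x**2))
    x *= 10.0 ** (drawn["peak_power_db"] / 20.0) / max(peak_rms, _EPS)
    return x, f


def synth_call(
    params: SynthCallParams, rng_seed: int | np.random.Generator = 0,
    pad_s: float = 0.05,
) -> tuple[AudioClip, CallTruth]:
    """Synthesize one call element with ground truth.

    Deterministic: the same seed yields a bit-identical waveform. The
    call sits between ``pad_s`` of leading and trailing silence.
    """
    rng = np.random.default_rng(rng_seed)
    drawn = draw_call_descriptors(params, rng)
    x, f = _call_waveform(params, drawn, rng)
    sr = params.sample_rate
    pad = int(round(pad_s * sr))
    samples = np.concatenate([np.zeros(pad), x, np.zeros(pad)])
    onset = pad / sr
    truth = CallTruth(
        onset_s=onset,
        offset_s=onset + x.size / sr,
        f0_times_s=onset + np.arange(x.size) / sr,
        f0_hz=f,
        drawn=drawn,
    )
    return AudioClip(samples, sr), truth


def synth_background(
    kind: str = "mixed",
    duration_s: float = 3.0,
    rng_seed: int | np.random.Generator = 0,
    rate: int = 16000,
    level_db: float = -55.0,
) -> AudioClip:
    """Vocalization-free background audio.

    ``noise`` is ventilation-like low-frequency-weighted noise,
    ``hum`` a 50 Hz-harmonic mains tone stack, ``mixed`` their sum.
    By construction no concentrated harmonic energy falls in the
    1-6 kHz call band.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if kind not in ("noise", "hum", "mixed"):
        raise ValueError(f"unknown background kind {kind!r}")
    rng = np.random.default_rng(rng_seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)
    if kind in ("noise", "mixed"):
        w = rng.standard_normal(n)
        b, a = butter(2, 300.0 / (rate / 2), "low")
        rumble = lfilter(b, a, w)
        broad = 0.03 * rng.standard_normal(n)
        # slow level modulation so the background is non-stationary
        mod = 1.0 + 0.2 * np.sin(2 * np.pi * rng.uniform(0.1, 0.4) * t
                                 + rng.uniform(0, 2 * np.pi))
        x += (rumble / max(np.std(rumble), _EPS) + broad) * mod
    if kind in ("hum", "mixed"):
        hum = np.zeros(n)
        for h in range(1, 9):  # 50..400 Hz
            hum += (1.0 / h) * np.sin(2 * np.pi * 50.0 * h * t
                                      + rng.uniform(0, 2 * np.pi))
        scale = 1.0 if kind == "hum" else 0.3
        x += scale * hum / max(np.std(hum), _EPS)
        if kind == "hum":
            x += 0.01 * rng.standard_normal(n)
    x *= 10.0 ** (level_db / 20.0) / max(np.sqrt(np.mean(x**2)), _EPS)
    return AudioClip(x, rate)


def _other_sound(rng, rate, level_db):
    """Inharmonic noise-burst 'other sound' (e.g. pecking, scratching)."""
    dur = float(rng.uniform(0.2, 0.5))
    n = int(round(dur * rate))
    w = rng.standard_normal(n)
    b, a = butter(2, [1500.0 / (rate / 2), 3500.0 / (rate / 2)], "band")
    x = lfilter(b, a, w)
    t = np.arange(n) / rate
    env = np.sin(np.pi * t / dur) ** 2
    x *= env
    win = max(1, int(round(0.010 * rate)))
    m = n // win
    rms = np.sqrt(np.mean(x[: m * win].reshape(m, win) ** 2, axis=1))
    x *= 10.0 ** (level_db / 20.0) / max(rms.max(), _EPS)
    return x, dur


def make_dataset(
    n_per_class_week: int,
    weeks=(1, 2, 3, 4, 5),
    include_background: bool = True,
    rng_seed: int = 0,
    snr_db: float = 15.0,
    clip_s: float = 2.0,
    rate: int = 16000,
    classes=CLASSES_5,
) -> tuple[list[LabeledSample], pd.DataFrame]:
    """Balanced labeled dataset of synthetic clips plus ground truth.

    Each clip embeds one call (or one distress bout) in low-level
    background noise at ``snr_db`` (call peak RMS over background RMS,
    dB). Age in days is drawn uniformly within the sample's week.
    Pleasure-note cells for weeks 4-5 are skipped (no parameters exist
    for them), mirroring their absence from the source data; requesting
    them explicitly via :meth:`SynthCallParams.from_table` raises.
    """
    if n_per_class_week < 1:
        raise ValueError("n_per_class_week must be >= 1")
    weeks = tuple(weeks)
    for w in weeks:
        if not 1 <= w <= 5:
            raise ValueError(f"week must be in 1..5, got {w}")
    rng = np.random.default_rng(rng_seed)
    samples: list[LabeledSample] = []
    rows = []
    cells = [(c, w) for c in classes for w in weeks
             if not (c == "pleasure" and w not in TABLE3_STATS["pleasure"])]
    if include_background:
        cells += [("background", w) for w in weeks]
    for label, week in cells:
        for i in range(n_per_class_week):
            idx = len(samples)
            n = int(round(clip_s * rate))
            if label == "background":
                kind = ("noise", "hum", "mixed")[int(rng.integers(3))]
                clip = synth_background(kind, clip_s, rng, rate,
                                        level_db=float(rng.uniform(-65, -50)))
                samples.append(LabeledSample(clip, "background", None))
                rows.append({"index": idx, "label": label, "week": week,
                             "age_days": np.nan, "onset_s": np.nan,
                             "offset_s": np.nan, "n_calls": 0})
                continue
            lo, hi = week_age_range(week)
            age = int(rng.integers(lo, hi + 1))
            if label == "other":
                level = float(
                    _trunc_draw(rng, *OTHER_STATS.peak_power_db, -90, -3, 2.5)
                )
                x, dur = _other_sound(rng, rate, level)
                call_peak_db = level
                drawn = {"duration_s": dur, "peak_power_db": level,
                         "f0_hz": np.nan, "trend_hz_per_10ms": np.nan,
                         "bout_n": 1, "bow_depth_hz": 0.0}
                events = [x]
                gaps = []
            else:
                params = SynthCallParams.from_table(label, week)
                params = replace(params, sample_rate=rate)
                drawn = draw_call_descriptors(params, rng)
                call_peak_db = drawn["peak_power_db"]
                events, gaps = [], []
                for b in range(drawn["bout_n"]):
                    jitter = dict(drawn)
                    if b > 0:  # bout repetitions carry small jitter
                        jitter["duration_s"] = max(
                            0.05, drawn["duration_s"] * float(rng.normal(1, 0.05))
                        )
                        jitter["f0_hz"] = float(
                            np.clip(drawn["f0_hz"] * rng.normal(1, 0.02), *F0_BOUNDS)
                        )
                    xe, _ = _call_waveform(params, jitter, rng)
                    events.append(xe)
                    gaps.append(float(rng.uniform(*params.bout_gap_s)))

            total = sum(e.size for e in events) + int(
                sum(gaps[: len(events) - 1]) * rate
            )
            if total > n - int(0.1 * rate):  # keep a margin inside the clip
                n = total + int(0.2 * rate)
            bed = synth_background(
                "mixed", n / rate, rng, rate,
                level_db=call_peak_db - snr_db,
            )
            sig = bed.samples.copy()
            start = int(rng.integers(int(0.05 * rate),
                                     max(n - total - int(0.05 * rate), 1)))
            pos = start
            onsets, offsets = [], []
            for k, e in enumerate(events):
                sig[pos : pos + e.size] += e
                onsets.append(pos / rate)
                offsets.append((pos + e.size) / rate)
                if k < len(events) - 1:
                    pos += e.size + int(gaps[k] * rate)
            clip = AudioClip(np.clip(sig, -1, 1), rate)
            samples.append(LabeledSample(clip, label, age))
            rows.append({"index": idx, "label": label, "week": week,
                         "age_days": age, "onset_s": onsets[0],
                         "offset_s": offsets[-1], "n_calls": len(events),
                         **{k: v for k, v in drawn.items()}})
    truth = pd.DataFrame(rows)
    return samples, truth


def write_dataset(samples, truth: pd.DataFrame, out_dir) -> pd.DataFrame:
    """Write a WAV tree + manifest.csv + truth.csv; returns the manifest."""
    import os

    from .audio import write_wav

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        rel = f"{s.label}_{i:05d}.wav"
        write_wav(os.path.join(out_dir, rel), s.clip)
        rows.append({"path": rel, "label": s.label,
                     "age_days": s.age_days if s.age_days is not None else ""})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    truth.to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    return manifest
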