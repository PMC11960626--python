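"""Acoustic call features: segmentation, fundamental frequency, summaries.

Individual calls are cut from a clip with a short-windowed power
envelope and dynamic (level-relative) thresholding, then described by
four features:

* ``length_s`` — call duration in seconds;
* ``max_power_db`` — maximum of the 10 ms RMS power envelope, in dB
  relative to digital full scale;
* ``f0_hz`` — fundamental frequency at the frame of maximal energy;
* ``f0_trend_hz_per_10ms`` — change of f0 across the call, expressed in
  Hz per 10 ms (positive = ascending pitch, negative = descending).

The f0 tracker is a YIN-family estimator: cumulative mean normalized
difference function per 10 ms frame, trough candidates weighted by
aperiodicity, a Viterbi pass that discourages octave jumps, and a
spectral-autocorrelation refinement that resolves sub-sample lags (the
fundamental of young-chick calls sits near 3 kHz, barely five samples
of period at 16 kHz). The trend is the least-squares slope of voiced
f0 against time (an endpoint-difference estimator is available via
``FeatureConfig.trend_estimator``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .audio import AudioClip

__all__ = [
    "FeatureConfig",
    "CallSegment",
    "CallFeatureRecord",
    "UnvoicedCallError",
    "power_envelope",
    "segment_calls",
    "estimate_f0_track",
    "extract_features",
    "summarize_features",
    "records_to_frame",
]

_EPS = 1e-12
FEATURE_NAMES = ("length_s", "max_power_db", "f0_hz", "f0_trend_hz_per_10ms")


class UnvoicedCallError(ValueError):
    """Raised when a call has too few voiced frames for f0 features."""


@dataclass
class FeatureConfig:
    env_window_s: float = 0.010       # RMS window of the power envelope
    env_smooth_frames: int = 5        # envelope smoothing extent
    threshold_frac: float = 0.25      # dynamic threshold position above floor
    floor_percentile: float = 20.0    # noise-floor percentile of the envelope
    hysteresis_db: float = 3.0        # offset threshold sits this far below onset
    min_call_s: float = 0.030
    merge_gap_s: float = 0.020
    min_dynamic_range_db: float = 12.0  # below this envelope span: no calls
    f0_min_hz: float = 400.0
    f0_max_hz: float = 6000.0
    f0_frame_s: float = 0.032         # analysis frame for the f0 tracker
    f0_hop_s: float = 0.010
    voicing_threshold: float = 0.40   # CMNDF aperiodicity bound for voicing
    trend_estimator: str = "regression"  # 'regression' | 'endpoint'


DEFAULT_FEATURES = FeatureConfig()


@dataclass(frozen=True)
class CallSegment:
    start_s: float
    end_s: float
    peak_power_time_s: float

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class CallFeatureRecord:
    length_s: float
    max_power_db: float
    f0_hz: float
    f0_trend_hz_per_10ms: float


# ---------------------------------------------------------------------------
# envelope + segmentation
# ---------------------------------------------------------------------------


def power_envelope(
    clip: AudioClip, config: FeatureConfig = DEFAULT_FEATURES
) -> tuple[np.ndarray, np.ndarray]:
    """Short-windowed smoothed RMS envelope in dB re full scale.

    Returns ``(times_s, env_db)`` with one value per 10 ms hop.
    """
    win = max(1, int(round(config.env_window_s * clip.rate)))
    n = len(clip) // win
    if n == 0:
        return np.empty(0), np.empty(0)
    x = clip.samples[: n * win].reshape(n, win)
    rms = np.sqrt(np.mean(x**2, axis=1))
    db = 20.0 * np.log10(rms + _EPS)
    db = uniform_filter1d(db, size=config.env_smooth_frames, mode="nearest")
    times = (np.arange(n) + 0.5) * win / clip.rate
    return times, db


def segment_calls(
    clip: AudioClip, config: FeatureConfig = DEFAULT_FEATURES
) -> list[CallSegment]:
    """Cut individual calls with dynamic thresholding of the envelope.

    The onset threshold sits at ``floor + threshold_frac * (peak -
    floor)`` in dB, where the floor is a low percentile of the envelope
    — so segmentation is invariant to overall amplitude scaling. The
    offset threshold sits ``hysteresis_db`` lower. Segments closer than
    ``merge_gap_s`` are merged, segments shorter than ``min_call_s``
    dropped. Silence (or any clip whose envelope spans less than
    ``min_dynamic_range_db``) yields no calls.
    """
    times, env = power_envelope(clip, config)
    if env.size == 0:
        return []
    floor = np.percentile(env, config.floor_percentile)
    peak = env.max()
    if peak - floor < config.min_dynamic_range_db:
        return []
    thr_on = floor + config.threshold_frac * (peak - floor)
    thr_off = thr_on - config.hysteresis_db

    hop = times[1] - times[0] if times.size > 1 else config.env_window_s
    raw = []
    inside = False
    start = 0
    for i, v in enumerate(env):
        if not inside and v >= thr_on:
            inside, start = True, i
        elif inside and v < thr_off:
            raw.append((start, i))
            inside = False
    if inside:
        raw.append((start, env.size))

    merged = []
    for s, e in raw:
        if merged and (s - merged[-1][1]) * hop <= config.merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    segments = []
    for s, e in merged:
        t0, t1 = times[s] - hop / 2, times[e - 1] + hop / 2
        if t1 - t0 < config.min_call_s:
            continue
        pk = s + int(np.argmax(env[s:e]))
        segments.append(CallSegment(t0, t1, times[pk]))
    return segments


# ---------------------------------------------------------------------------
# fundamental-frequency tracking (YIN family)
# ---------------------------------------------------------------------------


def _cmndf(frame: np.ndarray, tau_max: int) -> np.ndarray:
    """Cumulative mean normalized difference function for lags 1..tau_max."""
    w = frame.size - tau_max
    n_fft = int(2 ** np.ceil(np.log2(frame.size + tau_max)))
    fx = np.fft.rfft(frame, n_fft)
    acf = np.fft.irfft(fx * np.conj(fx), n_fft)[: tau_max + 1]
    csum = np.cumsum(frame**2)
    e0 = csum[w - 1]
    e_tau = csum[w - 1 + np.arange(tau_max + 1)] - np.concatenate(
        ([0.0], csum[: tau_max])
    )
    d = e0 + e_tau - 2.0 * acf
    d = np.maximum(d[1:], 0.0)
    running = np.cumsum(d) / np.arange(1, tau_max + 1)
    return d / np.maximum(running, _EPS)


def _refine_lag(frame: np.ndarray, tau: float, span: float = 1.0) -> float:
    """Maximize the exact (spectral) autocorrelation near an integer lag.

    r(tau) at fractional lags is evaluated from the power spectrum,
    which resolves the sub-sample periods of high-pitched calls.
    """
    n_fft = int(2 ** np.ceil(np.log2(frame.size * 2)))
    p = np.abs(np.fft.rfft(frame, n_fft)) ** 2
    k = np.arange(p.size)

    def r(t):
        return float(np.sum(p * np.cos(2 * np.pi * k * t / n_fft)))

    grid = np.linspace(tau - span, tau + span, 41)
    vals = [r(t) for t in grid]
    i = int(np.argmax(vals))
    lo, hi = max(0, i - 1), min(len(grid) - 1, i + 1)
    fine = np.linspace(grid[lo], grid[hi], 21)
    vals = [r(t) for t in fine]
    return float(fine[int(np.argmax(vals))])


def _frame_candidates(
    cm: np.ndarray, tau_min: int, voicing_threshold: float,
    yin_threshold: float = 0.20,
):
    """Trough candidates (lag, aperiodicity) of a CMNDF curve.

    Follows the YIN selection rule: when troughs fall below the absolute
    threshold, the shortest such lag is the fundamental and deeper
    troughs at its integer multiples (octave-down errors) are discarded.
    """
    cands = []
    idx = np.flatnonzero(
        (cm[1:-1] < cm[:-2]) & (cm[1:-1] <= cm[2:])
        & (cm[1:-1] < voicing_threshold * 2)
    ) + 1
    cands = [(i + 1, cm[i]) for i in idx if i + 1 >= tau_min]
    below = [c for c in cands if c[1] < yin_threshold]
    if below:
        lag0 = min(lag for lag, _ in below)
        kept = [c for c in below if c[0] < 1.5 * lag0]
        return kept or below[:1]
    return cands


def estimate_f0_track(
    clip: AudioClip,
    segment: CallSegment | None = None,
    config: FeatureConfig = DEFAULT_FEATURES,
) -> pd.DataFrame:
    """Per-frame f0 estimates on 10 ms frames within a segment.

    Returns a DataFrame with columns ``time_s``, ``f0_hz`` (NaN when
    unvoiced) and ``voiced``. Candidate periods come from CMNDF troughs,
    a Viterbi pass picks a smooth path (penalizing octave jumps), and
    selected lags are refined against the exact autocorrelation. Raises
    ``ValueError`` for segments shorter than 3 frames.
    """
    sr = clip.rate
    t0 = segment.start_s if segment else 0.0
    t1 = segment.end_s if segment else clip.duration
    if t1 > clip.duration + 1e-9 or t0 < -1e-9:
        raise ValueError("segment lies outside the clip")
    # 4x band-limited upsampling: young-chick fundamentals near 3 kHz
    # have sub-6-sample periods at 16 kHz, too coarse for integer lags
    ups = 4
    sru = sr * ups
    frame_len = int(round(config.f0_frame_s * sr))
    tau_max = int(np.ceil(sru / config.f0_min_hz))
    tau_min = max(2, int(np.floor(sru / config.f0_max_hz)))
    need = frame_len + int(np.ceil(tau_max / ups))

    centers = np.arange(t0 + config.f0_hop_s / 2, t1 - 1e-9, config.f0_hop_s)
    if centers.size < 3:
        raise ValueError(
            f"segment of {t1 - t0:.3f} s has fewer than 3 analysis frames"
        )

    from scipy.signal import resample as _resample_fft

    x = clip.samples
    cands_per_frame = []
    frames = []
    for tc in centers:
        c = int(round(tc * sr))
        lo = max(0, c - need // 2)
        fr = x[lo : lo + need]
        if fr.size < need:
            fr = np.pad(fr, (0, need - fr.size))
        fru = _resample_fft(fr, fr.size * ups)
        frames.append(fru)
        if np.sqrt(np.mean(fru**2)) < 1e-6:
            cands_per_frame.append([])
            continue
        cm = _cmndf(fru, tau_max)
        cands_per_frame.append(
            _frame_candidates(cm, tau_min, config.voicing_threshold)
        )

    # Viterbi over trough candidates; emission favors periodic troughs,
    # transition penalizes large pitch jumps (octave errors).
    path = _viterbi_lags(cands_per_frame, sru)

    rows = []
    for tc, fru, cands, tau in zip(centers, frames, cands_per_frame, path):
        voiced = False
        f0 = np.nan
        if tau is not None:
            cm_at = dict((lag, v) for lag, v in cands)[tau]
            if cm_at < config.voicing_threshold:
                tau_ref = _refine_lag(fru, float(tau), span=float(ups))
                f0 = sru / tau_ref
                voiced = (
                    config.f0_min_hz * 0.9 <= f0 <= config.f0_max_hz * 1.1
                )
        rows.append(
            {
                "time_s": tc,
                "f0_hz": f0 if voiced else np.nan,
                "voiced": bool(voiced),
            }
        )
    return pd.DataFrame(rows)


def _viterbi_lags(cands_per_frame, sr, jump_penalty: float = 4.0):
    """Smoothest lag path through per-frame trough candidates.

    Frames without candidates break the track into independent voiced
    runs; within a run the path minimizes aperiodicity plus a penalty
    on log-pitch jumps.
    """
    path = [None] * len(cands_per_frame)
    i = 0
    while i < len(cands_per_frame):
        if not cands_per_frame[i]:
            i += 1
            continue
        j = i
        while j < len(cands_per_frame) and cands_per_frame[j]:
            j += 1
        scores, backptr, prev_lags = None, [], None
        for k in range(i, j):
            lags = np.array([c[0] for c in cands_per_frame[k]], dtype=float)
            emit = np.array([c[1] for c in cands_per_frame[k]])
            if scores is None:
                scores = emit.copy()
                backptr.append(np.full(lags.size, -1, dtype=int))
            else:
                trans = jump_penalty * np.abs(
                    np.log2(lags[None, :] / prev_lags[:, None])
                )
                total = scores[:, None] + trans + emit[None, :]
                choice = np.argmin(total, axis=0)
                scores = total[choice, np.arange(lags.size)]
                backptr.append(choice)
            prev_lags = lags
        state = int(np.argmin(scores))
        for k in range(j - 1, i - 1, -1):
            path[k] = cands_per_frame[k][state][0]
            if backptr[k - i][state] >= 0:
                state = int(backptr[k - i][state])
        i = j
    return path


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


def extract_features(
    clip: AudioClip,
    segment: CallSegment,
    f0_track: pd.DataFrame | None = None,
    config: FeatureConfig = DEFAULT_FEATURES,
) -> CallFeatureRecord:
    """The four-feature description of one call.

    Raises :class:`UnvoicedCallError` when fewer than 3 frames are
    voiced (such calls are skipped and logged by callers).
    """
    if f0_track is None:
        f0_track = estimate_f0_track(clip, segment, config)
    voiced = f0_track[f0_track["voiced"]]
    if len(voiced) < 3:
        raise UnvoicedCallError(
            f"call at {segment.start_s:.3f}s has {len(voiced)} voiced frames (<3)"
        )
    times, env = power_envelope(clip, config)
    in_seg = (times >= segment.start_s) & (times <= segment.end_s)
    max_power_db = float(env[in_seg].max()) if in_seg.any() else float(env.max())

    # f0 at the frame of maximal energy (nearest voiced frame to the
    # envelope peak within the segment)
    peak_t = segment.peak_power_time_s
    vt = voiced["time_s"].to_numpy()
    f0_at_peak = float(voiced["f0_hz"].to_numpy()[np.argmin(np.abs(vt - peak_t))])

    vf = voiced["f0_hz"].to_numpy()
    if config.trend_estimator == "endpoint":
        slope = (vf[-1] - vf[0]) / max(vt[-1] - vt[0], _EPS)
    else:
        slope = float(np.polyfit(vt, vf, 1)[0])
    return CallFeatureRecord(
        length_s=segment.length_s,
        max_power_db=max_power_db,
        f0_hz=f0_at_peak,
        f0_trend_hz_per_10ms=slope * 0.010,
    )


def records_to_frame(records) -> pd.DataFrame:
    """(class, week, record) tuples -> tidy feature DataFrame."""
    rows = [
        {"class": c, "week": w, **vars(r)} for c, w, r in records
    ]
    return pd.DataFrame(rows)


def summarize_features(records) -> pd.DataFrame:
    """Per-(class, week) mean and sample SD of each feature.

    ``records`` holds (class, week, CallFeatureRecord) tuples. Cells
    with a single record report SD 0; empty cells are omitted. Output
    rows are indexed by (class, week) with ``<feature>_mean`` /
    ``<feature>_sd`` columns.
    """
    df = records_to_frame(records)
    if df.empty:
        return pd.DataFrame()
    out = []
    for (cls, week), g in df.groupby(["class", "week"]):
        row = {"class": cls, "week": week, "n": len(g)}
        for feat in FEATURE_NAMES:
            row[f"{feat}_mean"] = g[feat].mean()
            row[f"{feat}_sd"] = g[feat].std(ddof=1) if len(g) > 1 else 0.0
        out.append(row)
    return pd.DataFrame(out).set_index(["class", "week"]).sort_index()
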