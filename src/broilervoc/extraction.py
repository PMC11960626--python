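"""Candidate-vocalization segment extraction from tagger likelihoods.

An external audio tagger (any model scoring AudioSet-style labels per
second) produces a :class:`TagLikelihoodSeries`. Seconds whose maximum
likelihood over the configured bird/fowl label subset exceeds a marking
threshold (0.2) are marked, consecutive marked seconds are grouped,
each group is padded by one second on both sides, overlapping or
touching padded intervals are consolidated, and only consolidated
segments whose peak likelihood reaches the retention threshold (0.3)
are kept. The tagger itself is pluggable; this module only consumes its
per-second scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio import AudioClip

__all__ = [
    "DEFAULT_TAG_LABELS",
    "TagLikelihoodSeries",
    "SegmentProposal",
    "propose_segments",
    "consolidate",
    "clip_segments",
    "read_likelihoods",
    "write_segments_csv",
]

DEFAULT_TAG_LABELS = (
    "Fowl",
    "Chicken, rooster",
    "Bird",
    "Bird vocalization, bird call, bird song",
)


@dataclass
class TagLikelihoodSeries:
    """Per-second tag likelihoods for a set of labels.

    ``values`` has shape (n_seconds, n_labels) with entries in [0, 1];
    row ``s`` covers the second [s, s+1).
    """

    values: np.ndarray
    labels: tuple[str, ...] = DEFAULT_TAG_LABELS

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size and (
            self.values.min() < 0 or self.values.max() > 1
        ):
            raise ValueError("likelihoods must lie in [0, 1]")
        if self.values.shape[1] != len(self.labels):
            raise ValueError("one column per label required")

    @property
    def n_seconds(self) -> int:
        return self.values.shape[0]

    def per_second_max(self) -> np.ndarray:
        """Any-label exceedance statistic: max over labels per second."""
        return self.values.max(axis=1)


@dataclass(frozen=True)
class SegmentProposal:
    """A half-open [start_s, end_s) candidate segment in whole seconds."""

    start_s: int
    end_s: int
    peak_likelihood: float

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("end_s must exceed start_s")

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s


def propose_segments(
    series: TagLikelihoodSeries,
    mark_threshold: float = 0.2,
    keep_threshold: float = 0.3,
    pad_s: int = 1,
    max_length_s: int | None = None,
) -> list[SegmentProposal]:
    """Threshold / pad / consolidate / retain candidate segments.

    A second is marked iff its max likelihood strictly exceeds
    ``mark_threshold``; a consolidated segment is retained iff its peak
    is at least ``keep_threshold`` (non-strict). Equivalent to taking
    the union of the padded neighbourhoods of all marked seconds and
    keeping the connected components that reach the retention
    threshold. ``max_length_s`` optionally truncates over-long segments
    (off by default; long segments are an observed property, not an
    enforced cap).
    """
    if not 0 <= mark_threshold < keep_threshold <= 1:
        raise ValueError("thresholds must satisfy 0 <= mark < keep <= 1")
    n = series.n_seconds
    if n == 0:
        return []
    maxes = series.per_second_max()
    covered = np.zeros(n, dtype=bool)
    for s in np.flatnonzero(maxes > mark_threshold):
        covered[max(0, s - pad_s) : min(n, s + 1 + pad_s)] = True

    proposals = []
    s = 0
    while s < n:
        if not covered[s]:
            s += 1
            continue
        e = s
        while e < n and covered[e]:
            e += 1
        peak = float(maxes[s:e].max())
        if peak >= keep_threshold:
            end = min(e, s + max_length_s) if max_length_s else e
            proposals.append(SegmentProposal(s, end, peak))
        s = e
    return proposals


def consolidate(proposals: list[SegmentProposal]) -> list[SegmentProposal]:
    """Merge overlapping or touching proposals (idempotent)."""
    if not proposals:
        return []
    ordered = sorted(proposals, key=lambda p: p.start_s)
    merged = [ordered[0]]
    for p in ordered[1:]:
        last = merged[-1]
        if p.start_s <= last.end_s:
            merged[-1] = SegmentProposal(
                last.start_s,
                max(last.end_s, p.end_s),
                max(last.peak_likelihood, p.peak_likelihood),
            )
        else:
            merged.append(p)
    return merged


def clip_segments(
    clip: AudioClip, proposals: list[SegmentProposal]
) -> list[AudioClip]:
    """Cut one sub-clip per proposal at exact whole-second boundaries."""
    out = []
    for p in proposals:
        if p.start_s < 0 or p.end_s * clip.rate > len(clip):
            raise ValueError(
                f"proposal [{p.start_s}, {p.end_s}) s lies outside the "
                f"{clip.duration:.2f} s clip"
            )
        out.append(
            AudioClip(
                clip.samples[p.start_s * clip.rate : p.end_s * clip.rate].copy(),
                clip.rate,
            )
        )
    return out


def read_likelihoods(path, labels=DEFAULT_TAG_LABELS) -> TagLikelihoodSeries:
    """Read per-second likelihoods from long CSV (second,label,likelihood)
    or from JSON ``{label: [per-second values]}``."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            data = json.load(fh)
        n = max(len(v) for v in data.values())
        values = np.zeros((n, len(labels)))
        for j, lab in enumerate(labels):
            v = data.get(lab, [])
            values[: len(v), j] = v
        return TagLikelihoodSeries(values, tuple(labels))
    df = pd.read_csv(path)
    n = int(df["second"].max()) + 1
    values = np.zeros((n, len(labels)))
    for j, lab in enumerate(labels):
        sub = df[df["label"] == lab]
        values[sub["second"].to_numpy(dtype=int), j] = sub["likelihood"].to_numpy()
    return TagLikelihoodSeries(values, tuple(labels))


def write_segments_csv(proposals: list[SegmentProposal], path) -> None:
    pd.DataFrame(
        [
            {"start_s": p.start_s, "end_s": p.end_s, "peak": p.peak_likelihood}
            for p in proposals
        ]
    ).to_csv(path, index=False)
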