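"""Spike-train primitives: binarization, ISI statistics, segment masking.

A spike train is a sorted list of event times plus a recording duration.  All
analyses downstream work on the binarized 1 kHz sequence R(t); bin ``t``
covers ``[t/fs, (t+1)/fs)`` and holds the spike count in that bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import Trace

__all__ = [
    "SpikeTrain",
    "SegmentMask",
    "RestingStats",
    "binarize",
    "isi_stats",
    "mask_and_concatenate",
    "eye_position_window_mask",
    "quick_phase_mask_from_velocity",
]


@dataclass
class SpikeTrain:
    """Event times (seconds, strictly increasing) within ``[0, duration)``."""

    times: np.ndarray
    duration: float
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    @property
    def rate(self) -> float:
        return self.n_spikes / self.duration


@dataclass
class SegmentMask:
    """Sorted, non-overlapping half-open intervals ``[start, end)`` in seconds."""

    intervals: list = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        ivs = [(float(a), float(b)) for a, b in self.intervals]
        ivs.sort()
        for (a, b) in ivs:
            if b <= a:
                raise ValueError(f"degenerate interval [{a}, {b})")
        for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValueError("mask intervals overlap")
        self.intervals = ivs

    @property
    def total(self) -> float:
        return sum(b - a for a, b in self.intervals)

    def complement(self, duration: float) -> "SegmentMask":
        """Intervals of ``[0, duration)`` not covered by this mask."""
        out, t = [], 0.0
        for a, b in self.intervals:
            if a > t:
                out.append((t, min(a, duration)))
            t = max(t, b)
        if t < duration:
            out.append((t, duration))
        return SegmentMask(out, label=f"not_{self.label}" if self.label else "")

    def contains(self, t: float) -> bool:
        return any(a <= t < b for a, b in self.intervals)


@dataclass
class RestingStats:
    firing_rate: float
    cv: float
    isis: np.ndarray
    n_spikes: int
    sd_convention: str = "unbiased"


def binarize(train: SpikeTrain) -> np.ndarray:
    """Bin a spike train into counts on its 1 kHz (or ``sample_rate``) grid.

    The sequence length is ``round(duration * sample_rate)``; bins hold
    counts, not clipped occupancy, so two spikes in one bin yield 2.
    """
    n = int(round(train.duration * train.sample_rate))
    out = np.zeros(n, dtype=float)
    if train.times.size:
        idx = np.floor(train.times * train.sample_rate).astype(int)
        idx = np.clip(idx, 0, n - 1)
        np.add.at(out, idx, 1.0)
    return out


def isi_stats(train: SpikeTrain) -> RestingStats:
    """Firing rate and ISI coefficient of variation.

    CV is the standard deviation over the mean of the interspike-interval
    distribution; the SD uses the unbiased (n-1) convention, recorded in the
    output metadata.  Requires at least 3 spikes (2 intervals).
    """
    if train.n_spikes < 3:
        raise ValueError("insufficient events: need >= 3 spikes for ISI CV")
    isis = np.diff(train.times)
    cv = float(np.std(isis, ddof=1) / np.mean(isis))
    return RestingStats(
        firing_rate=train.rate, cv=cv, isis=isis, n_spikes=train.n_spikes,
    )


def _mask_to_sample_segments(keep: SegmentMask, n: int, fs: float):
    """Convert kept intervals to sample index ranges [(i0, i1), ...]."""
    segs = []
    for a, b in keep.intervals:
        i0 = int(round(a * fs))
        i1 = int(round(b * fs))
        i0, i1 = max(0, i0), min(n, i1)
        if i1 > i0:
            segs.append((i0, i1))
    return segs


def mask_and_concatenate(x, keep: SegmentMask):
    """Keep only the masked epochs and abut them in a new time base.

    Works on a :class:`Trace` or a :class:`SpikeTrain`.  Returns
    ``(masked, boundaries)`` where ``boundaries`` is the list of sample-index
    ranges ``[(start, end), ...]`` of the original segments inside the new
    concatenated time base — spectral code uses it so that estimation windows
    never straddle a concatenation seam.
    """
    if not keep.intervals:
        raise ValueError("empty retained set")
    if isinstance(x, Trace):
        segs = _mask_to_sample_segments(keep, x.n_samples, x.sample_rate)
        if not segs:
            raise ValueError("empty retained set")
        parts = [x.values[i0:i1] for i0, i1 in segs]
        new = Trace(np.concatenate(parts), x.sample_rate, x.units)
        bounds, pos = [], 0
        for p in parts:
            bounds.append((pos, pos + p.size))
            pos += p.size
        return new, bounds
    if isinstance(x, SpikeTrain):
        new_times, bounds = [], []
        offset = 0.0
        fs = x.sample_rate
        for a, b in keep.intervals:
            a, b = max(0.0, a), min(x.duration, b)
            if b <= a:
                continue
            sel = x.times[(x.times >= a) & (x.times < b)]
            new_times.append(sel - a + offset)
            i0 = int(round(offset * fs))
            i1 = int(round((offset + b - a) * fs))
            bounds.append((i0, i1))
            offset += b - a
        if offset <= 0:
            raise ValueError("empty retained set")
        times = np.concatenate(new_times) if new_times else np.array([])
        return SpikeTrain(times, duration=offset, sample_rate=fs), bounds
    raise TypeError(f"cannot mask object of type {type(x).__name__}")


def eye_position_window_mask(eye_position: Trace, limit_deg: float = 5.0) -> SegmentMask:
    """Intervals during which the eye position stays within ``±limit_deg``."""
    inside = np.abs(eye_position.values) <= limit_deg
    fs = eye_position.sample_rate
    intervals = []
    edges = np.flatnonzero(np.diff(inside.astype(int)))
    starts = [0] if inside[0] else []
    for e in edges:
        if inside[e + 1]:
            starts.append(e + 1)
        else:
            intervals.append((starts.pop() / fs, (e + 1) / fs))
    if starts:
        intervals.append((starts.pop() / fs, inside.size / fs))
    return SegmentMask(intervals, label="eye_in_window")


def quick_phase_mask_from_velocity(
    eye_velocity: Trace, threshold: float = 100.0, pad_s: float = 0.01
) -> SegmentMask:
    """Simple velocity-threshold quick-phase detector.

    Marks epochs where |eye velocity| exceeds ``threshold`` (deg/s), padded by
    ``pad_s`` on each side; overlapping detections merge.  This is a
    configurable helper, not a full saccade classifier.
    """
    fast = np.abs(eye_velocity.values) > threshold
    fs = eye_velocity.sample_rate
    idx = np.flatnonzero(fast)
    if idx.size == 0:
        return SegmentMask([], label="quick_phase")
    intervals = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i > prev + 1:
            intervals.append((run_start, prev))
            run_start = i
        prev = i
    intervals.append((run_start, prev))
    n = eye_velocity.n_samples
    merged = []
    for i0, i1 in intervals:
        a = max(0.0, i0 / fs - pad_s)
        b = min(n / fs, (i1 + 1) / fs + pad_s)
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return SegmentMask(merged, label="quick_phase")
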