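"""Event alignment, overlap splitting, and per-event / per-recording stats."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from .detection import EventLocation
from .filtering import hann_points_for_rate, smooth_hann
from .trace import Trace

__all__ = ["EventSegment", "EventStats", "RecordingSummary", "align_events",
           "measure_event", "summarize_recording"]

#: fraction of the extraction window kept before the steepest-rise point
RISE_OFFSET_FRACTION = 0.25
#: derivative peaks with at least this prominence relative to the largest
#: one are treated as additional (overlapping) events
SPLIT_PROMINENCE_RATIO = 0.25


@dataclass
class EventSegment:
    """A window_len cutout of raw data aligned at its steepest rise."""

    samples: np.ndarray
    rise_offset: int          # index of the steepest-rise point in samples
    start_idx: int            # global sample index of samples[0]
    sampling_rate: float
    polarity: str = "negative"
    complete: bool = True     # False if truncated at a trace edge
    score: float = np.nan

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def rise_idx_global(self) -> int:
        return self.start_idx + self.rise_offset

    def sign(self) -> int:
        return 1 if self.polarity == "positive" else -1


@dataclass
class EventStats:
    amplitude: float          # signed, signal units
    rise_10_90_ms: float
    half_decay_ms: float
    charge: float             # signal units * ms
    peak_idx: int             # global sample index
    position_s: float
    score: float = np.nan
    valid_kinetics: bool = True


@dataclass
class RecordingSummary:
    n_events: int
    duration_s: float
    frequency_hz: float
    mean: dict = field(default_factory=dict)
    median: dict = field(default_factory=dict)


def _split_rises(segment: np.ndarray, sign: int, sampling_rate: float
                 ) -> np.ndarray:
    """Steepest-rise candidates within one segment via derivative peaks."""
    smooth_n = hann_points_for_rate(sampling_rate, base_points=10)
    deriv = np.gradient(smooth_hann(segment, smooth_n))
    if sign < 0:
        deriv = -deriv
    peaks, _ = find_peaks(deriv, height=0)
    if peaks.size == 0:
        return np.array([int(np.argmax(deriv))])
    prom = peak_prominences(deriv, peaks)[0]
    keep = prom >= SPLIT_PROMINENCE_RATIO * prom.max()
    return peaks[keep]


def align_events(trace: Trace, locations: list[EventLocation],
                 window_len: int = 600) -> list[EventSegment]:
    """Cut one aligned segment per event, splitting overlapping events.

    Within each extracted segment, additional derivative peaks with
    relative prominence >= 0.25 spawn extra events; duplicates (same
    steepest-rise sample) are merged.  Segments truncated by the trace
    edges are flagged ``complete=False``.
    """
    offset = int(round(RISE_OFFSET_FRACTION * window_len))
    n = len(trace)
    rises: dict[int, float] = {}
    for loc in sorted(locations, key=lambda l: l.steepest_rise_idx):
        start = loc.steepest_rise_idx - offset
        seg = trace.samples[max(start, 0):min(start + window_len, n)]
        if seg.size < 2:
            continue
        for r in _split_rises(seg, trace.sign(), trace.sampling_rate):
            g = int(max(start, 0) + r)
            if g not in rises:
                rises[g] = loc.peak_confidence
    segments = []
    for g in sorted(rises):
        start = g - offset
        stop = start + window_len
        complete = start >= 0 and stop <= n
        lo, hi = max(start, 0), min(stop, n)
        segments.append(EventSegment(
            samples=trace.samples[lo:hi], rise_offset=g - lo, start_idx=lo,
            sampling_rate=trace.sampling_rate, polarity=trace.polarity,
            complete=complete, score=rises[g]))
    return segments


def measure_event(segment: EventSegment, hann_points: int | None = None,
                  baseline_window: int = 50, baseline_gap: int = 10
                  ) -> EventStats:
    """Amplitude, 10-90% rise, half-decay and charge of one event.

    The segment is Hann-smoothed first (length auto-scaled with sampling
    rate unless given).  Amplitude is peak minus the mean of a short
    baseline window ending ``baseline_gap`` samples before the steepest
    rise.  Crossings are linearly interpolated between samples.
    """
    if hann_points is None:
        hann_points = hann_points_for_rate(segment.sampling_rate)
    if hann_points < 1:
        raise ValueError("hann_points must be >= 1")
    x = smooth_hann(segment.samples, hann_points)
    sign = segment.sign()
    dt_ms = 1e3 / segment.sampling_rate
    rise = segment.rise_offset

    b_stop = max(rise - baseline_gap, 0)
    b_start = max(b_stop - baseline_window, 0)
    baseline = float(np.mean(x[b_start:b_stop])) if b_stop > b_start \
        else float(x[0])

    if not segment.complete or x.size - rise < 2:
        peak_rel = int(np.argmax(sign * (x[rise:] - baseline))) + rise \
            if x.size > rise else rise
        amp = float(x[peak_rel] - baseline) if x.size else 0.0
        return EventStats(amplitude=amp, rise_10_90_ms=np.nan,
                          half_decay_ms=np.nan, charge=np.nan,
                          peak_idx=segment.start_idx + peak_rel,
                          position_s=segment.rise_idx_global
                          / segment.sampling_rate,
                          score=segment.score, valid_kinetics=False)

    y = sign * (x - baseline)          # positive-going, baseline-subtracted
    peak_rel = int(np.argmax(y[rise:])) + rise
    peak_y = y[peak_rel]
    amplitude = float(sign * peak_y)

    valid = peak_y > 0
    rise_ms = half_ms = np.nan
    if valid:
        t10 = _cross_before(y, peak_rel, 0.1 * peak_y)
        t90 = _cross_before(y, peak_rel, 0.9 * peak_y)
        if t10 is not None and t90 is not None and t90 > t10:
            rise_ms = (t90 - t10) * dt_ms
        t50 = _cross_after(y, peak_rel, 0.5 * peak_y)
        if t50 is not None:
            half_ms = (t50 - peak_rel) * dt_ms
    valid = valid and np.isfinite(rise_ms) and np.isfinite(half_ms)

    onset = _onset_index(y, rise)
    charge = float(sign * np.trapezoid(y[onset:], dx=dt_ms))

    return EventStats(amplitude=amplitude, rise_10_90_ms=float(rise_ms),
                      half_decay_ms=float(half_ms), charge=charge,
                      peak_idx=segment.start_idx + peak_rel,
                      position_s=segment.rise_idx_global
                      / segment.sampling_rate,
                      score=segment.score, valid_kinetics=bool(valid))


def _cross_before(y: np.ndarray, peak: int, level: float) -> float | None:
    """Interpolated index of the last upward crossing of level before peak."""
    below = np.flatnonzero(y[:peak + 1] < level)
    if below.size == 0 or below[-1] == peak:
        return None
    i = int(below[-1])
    y0, y1 = y[i], y[i + 1]
    frac = (level - y0) / (y1 - y0) if y1 != y0 else 0.0
    return i + float(frac)


def _cross_after(y: np.ndarray, peak: int, level: float) -> float | None:
    """Interpolated index of the first downward crossing of level after peak."""
    below = np.flatnonzero(y[peak:] < level)
    if below.size == 0:
        return None
    i = peak + int(below[0])
    if i == peak:
        return None
    y0, y1 = y[i - 1], y[i]
    frac = (y0 - level) / (y0 - y1) if y1 != y0 else 0.0
    return (i - 1) + float(frac)


def _onset_index(y: np.ndarray, rise: int) -> int:
    """Last baseline crossing before the steepest rise (charge onset)."""
    below = np.flatnonzero(y[:rise + 1] <= 0)
    return int(below[-1]) if below.size else 0


def summarize_recording(stats: list[EventStats], duration_s: float
                        ) -> RecordingSummary:
    """Frequency and nan-aware mean/median of each per-event statistic."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = len(stats)
    fields_ = ["amplitude", "rise_10_90_ms", "half_decay_ms", "charge"]
    mean, median = {}, {}
    for f in fields_:
        vals = np.array([getattr(s, f) for s in stats], dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        mean[f] = float(np.mean(vals)) if vals.size else np.nan
        median[f] = float(np.median(vals)) if vals.size else np.nan
    return RecordingSummary(n_events=n, duration_s=duration_s,
                            frequency_hz=n / duration_s, mean=mean,
                            median=median)
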