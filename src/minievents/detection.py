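"""Sliding-window inference over long traces and event localization."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.signal import find_peaks

from .filtering import hann_points_for_rate, smooth_hann
from .synth import minmax_scale
from .trace import Trace

__all__ = ["PredictionTrace", "EventLocation", "window_trace",
           "predict_trace", "locate_events"]

DEFAULT_STRIDE = 20
DEFAULT_MIN_HEIGHT = 0.5
DEFAULT_MIN_WIDTH = 5  # strides; the synthetic benchmark uses 10
LOCALIZE_HANN_POINTS = 60  # at 50 kHz; scaled with the sampling rate


@dataclass
class PredictionTrace:
    """Per-position classifier confidence derived at stride resolution.

    ``stride_values[k]`` is the score of the window starting at sample
    ``k * stride``; ``positions`` holds the sample index of each window
    center.  ``values`` is the score resampled to the source sampling
    rate by nearest-neighbor hold (edges take the nearest computed
    score, so its length equals the source trace length).
    """

    stride_values: np.ndarray
    stride: int
    window_len: int
    n_samples: int
    values: np.ndarray = field(init=False)
    resampled: bool = field(init=False, default=True)

    def __post_init__(self):
        self.stride_values = np.asarray(self.stride_values, dtype=np.float64)
        if self.stride_values.size and (self.stride_values.min() < 0
                                        or self.stride_values.max() > 1):
            raise ValueError("prediction values must lie in [0, 1]")
        if self.stride_values.size == 0:
            self.values = np.zeros(self.n_samples)
        else:
            self.values = self.stride_values[self._nearest_index(
                np.arange(self.n_samples))]

    @property
    def positions(self) -> np.ndarray:
        return (np.arange(self.stride_values.size) * self.stride
                + self.window_len // 2)

    def _nearest_index(self, sample_idx: np.ndarray) -> np.ndarray:
        k = np.round((np.asarray(sample_idx) - self.window_len // 2)
                     / self.stride).astype(int)
        return np.clip(k, 0, self.stride_values.size - 1)

    def to_sample_index(self, stride_idx) -> np.ndarray:
        return np.asarray(stride_idx) * self.stride + self.window_len // 2


@dataclass(frozen=True)
class EventLocation:
    threshold_crossing_idx: int
    steepest_rise_idx: int
    peak_confidence: float


def window_trace(trace: Trace, window_len: int = 600,
                 stride: int = DEFAULT_STRIDE) -> np.ndarray:
    """Cut a trace into overlapping windows, each min-max scaled to [0, 1].

    Returns floor((len - window_len) / stride) + 1 windows; a constant
    window maps to all zeros.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = len(trace)
    if n < window_len:
        raise ValueError(
            f"trace has {n} samples but the window length is {window_len}")
    view = np.lib.stride_tricks.sliding_window_view(trace.samples, window_len)
    return minmax_scale(view[::stride])


def predict_trace(model, trace: Trace, stride: int = DEFAULT_STRIDE,
                  batch_size: int = 128) -> PredictionTrace:
    """Run batched sliding-window inference and build the prediction trace."""
    windows = window_trace(trace, model.window_len, stride)
    scores = model.predict(windows, batch_size=batch_size)
    return PredictionTrace(np.clip(scores, 0.0, 1.0), stride,
                           model.window_len, len(trace))


def _threshold_crossing(values: np.ndarray, peak_idx: int,
                        height: float) -> int:
    """Last upward crossing of ``height`` at or before the peak."""
    below = np.flatnonzero(values[:peak_idx + 1] < height)
    return int(below[-1] + 1) if below.size else 0


def locate_events(pred: PredictionTrace, trace: Trace,
                  min_height: float = DEFAULT_MIN_HEIGHT,
                  min_width: int = DEFAULT_MIN_WIDTH,
                  max_filter_width: int = 1) -> list[EventLocation]:
    """Find events as peaks of the maximum-filtered prediction trace.

    Peak search runs at stride resolution; for each retained peak the raw
    data after the threshold crossing is scanned for the steepest rise
    (extremum of the first derivative, sign per trace polarity).
    """
    if not 0 < min_height < 1:
        raise ValueError("min_height must lie strictly between 0 and 1")
    values = pred.stride_values
    if values.size == 0:
        return []
    filtered = maximum_filter1d(values, size=max(1, max_filter_width),
                                mode="nearest")
    peaks, props = find_peaks(filtered, height=min_height, width=min_width,
                              plateau_size=0)
    # heavier smoothing than for quantification: localization must beat
    # derivative noise, and the symmetric window adds no position bias
    smooth_n = hann_points_for_rate(trace.sampling_rate,
                                    base_points=LOCALIZE_HANN_POINTS)
    deriv = np.gradient(smooth_hann(trace.samples, smooth_n))
    if trace.sign() < 0:
        deriv = -deriv
    out: dict[int, EventLocation] = {}
    for p in peaks:
        cross = _threshold_crossing(filtered, p, min_height)
        start = int(pred.to_sample_index(cross))
        start = min(max(start, 0), len(trace) - 1)
        # the event rise sits between the crossing and shortly after the
        # peak position; searching further would pick up neighboring events
        stop = int(pred.to_sample_index(p)) + pred.window_len // 4
        stop = min(max(stop, start + 1), len(trace))
        rise = start + int(np.argmax(deriv[start:stop]))
        loc = EventLocation(threshold_crossing_idx=start,
                            steepest_rise_idx=rise,
                            peak_confidence=float(filtered[p]))
        # two prediction peaks resolving to one rise are the same event
        if rise not in out or out[rise].peak_confidence < loc.peak_confidence:
            out[rise] = loc
    return [out[r] for r in sorted(out)]
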