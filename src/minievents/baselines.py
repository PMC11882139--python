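"""Conventional detectors: template matching (sliding least-squares fit),
Wiener deconvolution, and a baseline-normalized finite-threshold method."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from scipy.ndimage import median_filter

from .synth import biexp_kernel
from .trace import Trace

__all__ = ["TemplateSpec", "DetectorResult", "make_biexp_template",
           "template_matching_detect", "deconvolution_detect",
           "finite_threshold_detect"]


@dataclass
class TemplateSpec:
    """An event template; ``waveform`` is peak-normalized (|extremum| = 1)
    and signed like the events it describes."""

    waveform: np.ndarray
    baseline: float = 0.0

    def __post_init__(self):
        self.waveform = np.asarray(self.waveform, dtype=np.float64)
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("template contains non-finite values")
        peak = np.abs(self.waveform).max()
        if peak == 0:
            raise ValueError("template is all zeros")
        if not np.isclose(peak, 1.0):
            self.waveform = self.waveform / peak

    def __len__(self) -> int:
        return self.waveform.size


@dataclass
class DetectorResult:
    detection_trace: np.ndarray
    event_indices: np.ndarray
    threshold_used: float

    def event_times(self, sampling_rate: float) -> np.ndarray:
        return self.event_indices / sampling_rate


def make_biexp_template(tau_rise_ms: float, tau_decay_ms: float,
                        sampling_rate: float, duration_ms: float = 10.0,
                        polarity: str = "negative") -> TemplateSpec:
    kern = biexp_kernel(tau_rise_ms, tau_decay_ms, 1e3 / sampling_rate,
                        duration_ms, normalize=True)
    sign = -1.0 if polarity == "negative" else 1.0
    return TemplateSpec(sign * kern)


def _sliding_sums(x: np.ndarray, n: int):
    c = np.concatenate([[0.0], np.cumsum(x)])
    return c[n:] - c[:-n]


def template_matching_detect(trace: Trace, template: TemplateSpec,
                             criterion_threshold: float = -4.0
                             ) -> DetectorResult:
    """Sliding optimal-scaling template fit with an SSE-based criterion.

    At each offset the template is fitted with free scale and offset in
    least squares; the detection criterion is scale / sqrt(SSE / (N - 2)).
    The template is signed like the events, so a match drives the raw
    criterion positive; the detection trace carries the sign of
    ``criterion_threshold`` (negative threshold for negative-going events),
    and events lie beyond the threshold in that direction, one per
    contiguous run of crossings at the offset of extreme criterion.
    """
    T = template.waveform
    N = T.size
    if N >= len(trace):
        raise ValueError("template must be shorter than the trace")
    y = trace.samples
    sum_T = T.sum()
    sum_T2 = (T * T).sum()
    denom = sum_T2 - sum_T ** 2 / N
    if denom <= 0:
        raise ValueError("template has zero variance")
    sum_Ty = _signal.fftconvolve(y, T[::-1], mode="valid")
    sum_y = _sliding_sums(y, N)
    sum_y2 = _sliding_sums(y * y, N)

    scale = (sum_Ty - sum_T * sum_y / N) / denom
    offset = (sum_y - scale * sum_T) / N
    sse = (sum_y2 + scale ** 2 * sum_T2 + N * offset ** 2
           - 2 * (scale * sum_Ty + offset * sum_y - scale * offset * sum_T))
    sse = np.maximum(sse, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = scale / np.sqrt(sse / (N - 2))
    # a perfect fit (SSE = 0, scale != 0) gives an infinite criterion and
    # stays; near-zero-variance windows carry no signal (the guard also
    # absorbs FFT round-off on silent stretches)
    var_y = sum_y2 - sum_y ** 2 / N
    silent = var_y <= 1e-12 * max(var_y.max(), 1e-300)
    crit[silent | np.isnan(crit)] = 0.0

    negative = criterion_threshold < 0
    if negative:
        crit = -crit
    beyond = crit <= criterion_threshold if negative \
        else crit >= criterion_threshold
    idx = _runs_to_indices(beyond, crit, pick="min" if negative else "max")
    return DetectorResult(detection_trace=crit, event_indices=idx,
                          threshold_used=criterion_threshold)


def _runs_to_indices(mask: np.ndarray, score: np.ndarray, pick: str
                     ) -> np.ndarray:
    """One index per contiguous True run, at the extreme score."""
    if not mask.any():
        return np.empty(0, dtype=int)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        stops = np.concatenate([stops, [mask.size]])
    fn = np.argmin if pick == "min" else np.argmax
    return np.array([s + fn(score[s:e]) for s, e in zip(starts, stops)],
                    dtype=int)


def deconvolution_detect(trace: Trace, template: TemplateSpec,
                         threshold_sd_mult: float = 5.0,
                         reg_fraction: float = 0.01,
                         lowpass_hz: float | None = None) -> DetectorResult:
    """Frequency-domain (Wiener) deconvolution of the trace by the template.

    The deconvolved trace is low-pass filtered and thresholded at a
    multiple of its own standard deviation; isolated peaks above the
    threshold are the events.  The spectral division is regularized with
    ``reg_fraction`` of the peak template power.
    """
    T = template.waveform
    if np.abs(T).max() == 0:
        raise ValueError("template is all zeros")
    n = len(trace)
    F = np.fft.rfft(T, n)
    power = np.abs(F) ** 2
    eps = reg_fraction * power.max()
    D = np.fft.irfft(np.fft.rfft(trace.samples) * np.conj(F) / (power + eps),
                     n)
    if lowpass_hz is None:
        lowpass_hz = trace.sampling_rate / 50.0  # 1 kHz at 50 kHz
    if lowpass_hz < trace.sampling_rate / 2:
        sos = _signal.butter(4, lowpass_hz, fs=trace.sampling_rate,
                             output="sos")
        D = _signal.sosfiltfilt(sos, D)
    sd = D.std()
    thr = threshold_sd_mult * sd
    if sd == 0:
        return DetectorResult(D, np.empty(0, dtype=int), thr)
    peaks, _ = _signal.find_peaks(D, height=thr)
    return DetectorResult(detection_trace=D, event_indices=peaks,
                          threshold_used=thr)


def finite_threshold_detect(trace: Trace, amp_threshold: float = -4.0,
                            baseline_ms: float = 10.0,
                            min_duration_ms: float = 0.5,
                            baseline_decimation: int | None = None
                            ) -> DetectorResult:
    """Running-baseline subtraction followed by amplitude thresholding.

    The baseline is a median filter of ``baseline_ms``; excursions beyond
    ``amp_threshold`` lasting at least ``min_duration_ms`` count as one
    event each.  For speed the median runs on a decimated copy of the
    trace and is linearly interpolated back (decimation auto-scales with
    the sampling rate; pass 1 to disable).
    """
    if (amp_threshold < 0) != (trace.polarity == "negative"):
        raise ValueError("threshold sign must match the trace polarity")
    y = trace.samples
    rate = trace.sampling_rate
    if baseline_decimation is None:
        baseline_decimation = max(1, int(round(rate / 5000.0)))
    d = baseline_decimation
    size = max(3, int(round(baseline_ms * 1e-3 * rate / d)) | 1)
    coarse = median_filter(y[::d], size=size, mode="nearest")
    baseline = np.interp(np.arange(y.size), np.arange(coarse.size) * d,
                         coarse)
    det = y - baseline
    beyond = det <= amp_threshold if amp_threshold < 0 else det >= amp_threshold
    min_run = max(1, int(round(min_duration_ms * 1e-3 * rate)))
    idx = _runs_to_indices_min_len(beyond, min_run)
    return DetectorResult(detection_trace=det, event_indices=idx,
                          threshold_used=amp_threshold)


def _runs_to_indices_min_len(mask: np.ndarray, min_len: int) -> np.ndarray:
    if not mask.any():
        return np.empty(0, dtype=int)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        stops = np.concatenate([stops, [mask.size]])
    keep = (stops - starts) >= min_len
    return starts[keep]
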