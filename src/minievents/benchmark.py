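"""Detector scoring: truth matching, precision/recall/F1, threshold sweeps,
and uniform detector adapters for the classifier and the baselines."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import baselines as _bl
from .detection import (DEFAULT_MIN_HEIGHT, DEFAULT_STRIDE, locate_events,
                        predict_trace)
from .synth import GroundTruth
from .trace import Trace

__all__ = ["BenchmarkMetrics", "match_to_truth", "detection_metrics",
           "threshold_sweep", "ClassifierDetector", "TemplateMatchingDetector",
           "DeconvolutionDetector", "FiniteThresholdDetector",
           "DEFAULT_MATCH_TOLERANCE_MS"]

DEFAULT_MATCH_TOLERANCE_MS = 2.0


@dataclass(frozen=True)
class BenchmarkMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def match_to_truth(detected_times, truth, tolerance_ms: float =
                   DEFAULT_MATCH_TOLERANCE_MS) -> tuple[int, int, int]:
    """Greedy one-to-one nearest matching of detections to true onsets.

    Candidate pairs within tolerance are taken closest-first; every truth
    event matches at most one detection.  Returns (TP, FP, FN).
    """
    if tolerance_ms <= 0:
        raise ValueError("tolerance must be positive")
    det = np.sort(np.asarray(detected_times, dtype=np.float64))
    tru = np.asarray(truth.onset_times if isinstance(truth, GroundTruth)
                     else truth, dtype=np.float64)
    tol = tolerance_ms / 1e3
    if det.size == 0 or tru.size == 0:
        return 0, int(det.size), int(tru.size)
    dist = np.abs(det[:, None] - tru[None, :])
    pairs = np.argwhere(dist <= tol)
    order = np.argsort(dist[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_d = np.zeros(det.size, dtype=bool)
    used_t = np.zeros(tru.size, dtype=bool)
    tp = 0
    for i, j in pairs[order]:
        if not used_d[i] and not used_t[j]:
            used_d[i] = used_t[j] = True
            tp += 1
    return tp, int(det.size - tp), int(tru.size - tp)


def detection_metrics(tp: int, fp: int, fn: int) -> BenchmarkMetrics:
    """Precision, recall and F1 from confusion counts.

    Conventions: all three are 1 when TP = FP = FN = 0 (nothing to find,
    nothing found); any undefined ratio in the presence of errors is 0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp == 0 and fp == 0 and fn == 0:
        return BenchmarkMetrics(0, 0, 0, 1.0, 1.0, 1.0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return BenchmarkMetrics(tp, fp, fn, precision, recall, f1)


# ---------------------------------------------------------------------------
# detector adapters: a detector exposes .default_threshold and
# .detect(trace, threshold=None) -> event times in seconds
# ---------------------------------------------------------------------------

class ClassifierDetector:
    """Sliding-window classifier detection with a cached prediction trace,
    so threshold sweeps re-run only the (cheap) peak search."""

    name = "classifier"

    def __init__(self, model, stride: int = DEFAULT_STRIDE,
                 min_height: float = DEFAULT_MIN_HEIGHT, min_width: int = 10,
                 max_filter_width: int = 1, batch_size: int = 128):
        self.model = model
        self.stride = stride
        self.default_threshold = min_height
        self.min_width = min_width
        self.max_filter_width = max_filter_width
        self.batch_size = batch_size
        self._cache: tuple[int, object] | None = None

    def prediction(self, trace: Trace):
        key = (id(trace), len(trace))
        if self._cache is None or self._cache[0] != key:
            pred = predict_trace(self.model, trace, self.stride,
                                 self.batch_size)
            self._cache = (key, pred)
        return self._cache[1]

    def locate(self, trace: Trace, threshold: float | None = None):
        thr = self.default_threshold if threshold is None else threshold
        return locate_events(self.prediction(trace), trace, min_height=thr,
                             min_width=self.min_width,
                             max_filter_width=self.max_filter_width)

    def detect(self, trace: Trace, threshold: float | None = None
               ) -> np.ndarray:
        locs = self.locate(trace, threshold)
        return np.array(sorted(l.steepest_rise_idx for l in locs)) \
            / trace.sampling_rate


class TemplateMatchingDetector:
    name = "template"

    def __init__(self, template: _bl.TemplateSpec,
                 criterion_threshold: float = -4.0):
        self.template = template
        self.default_threshold = criterion_threshold

    def detect(self, trace: Trace, threshold: float | None = None
               ) -> np.ndarray:
        thr = self.default_threshold if threshold is None else threshold
        res = _bl.template_matching_detect(trace, self.template, thr)
        return res.event_times(trace.sampling_rate)


class DeconvolutionDetector:
    name = "deconvolution"

    def __init__(self, template: _bl.TemplateSpec,
                 threshold_sd_mult: float = 5.0):
        self.template = template
        self.default_threshold = threshold_sd_mult

    def detect(self, trace: Trace, threshold: float | None = None
               ) -> np.ndarray:
        thr = self.default_threshold if threshold is None else threshold
        res = _bl.deconvolution_detect(trace, self.template, thr)
        return res.event_times(trace.sampling_rate)


class FiniteThresholdDetector:
    name = "threshold"

    def __init__(self, amp_threshold: float = -4.0):
        self.default_threshold = amp_threshold

    def detect(self, trace: Trace, threshold: float | None = None
               ) -> np.ndarray:
        thr = self.default_threshold if threshold is None else threshold
        res = _bl.finite_threshold_detect(trace, amp_threshold=thr)
        return res.event_times(trace.sampling_rate)


def threshold_sweep(detector, trace: Trace, truth: GroundTruth,
                    fractions=None,
                    tolerance_ms: float = DEFAULT_MATCH_TOLERANCE_MS
                    ) -> list[dict]:
    """Re-run a detector at scaled thresholds (percent of its default).

    Returns one row per fraction with the threshold used, the number of
    detections and the F1 score; a row that raises records NaNs and the
    sweep continues.
    """
    if fractions is None:
        fractions = np.arange(5, 196, 10)
    rows = []
    for frac in fractions:
        thr = detector.default_threshold * frac / 100.0
        row = {"fraction": float(frac), "threshold": float(thr)}
        try:
            times = detector.detect(trace, threshold=thr)
            m = detection_metrics(*match_to_truth(times, truth, tolerance_ms))
            row.update(n_detected=int(len(times)), f1=m.f1,
                       precision=m.precision, recall=m.recall)
        except Exception as exc:  # noqa: BLE001 - per-row isolation
            row.update(n_detected=np.nan, f1=np.nan, precision=np.nan,
                       recall=np.nan, error=str(exc))
        rows.append(row)
    return rows
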