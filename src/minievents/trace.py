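"""Continuous single-channel recordings and basic resampling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trace", "resample_trace"]


@dataclass
class Trace:
    """A uniformly sampled single-channel recording.

    Parameters
    ----------
    samples : ndarray
        Signal values (pA, mV or dF/F0).
    sampling_rate : float
        Sampling rate in Hz; must be positive.
    units : str
        Physical units of ``samples``.
    polarity : {"negative", "positive"}
        Direction of expected event deflections relative to baseline.
    """

    samples: np.ndarray
    sampling_rate: float
    units: str = "pA"
    polarity: str = "negative"
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.polarity not in ("negative", "positive"):
            raise ValueError("polarity must be 'negative' or 'positive'")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds (0-based)."""
        return np.arange(self.samples.size) / self.sampling_rate

    def sign(self) -> int:
        """+1 for positive-going events, -1 for negative-going events."""
        return 1 if self.polarity == "positive" else -1


def resample_trace(trace: Trace, factor: float) -> Trace:
    """Resample a trace by a rational factor using linear interpolation.

    The returned trace has ``sampling_rate * factor``; amplitudes at the
    original sample points are preserved exactly.
    """
    if not factor > 0:
        raise ValueError("resampling factor must be positive")
    if not np.all(np.isfinite(trace.samples)):
        raise ValueError("trace contains non-finite samples; cannot resample")
    if factor == 1:
        return Trace(trace.samples.copy(), trace.sampling_rate, trace.units,
                     trace.polarity, trace.name)
    n = trace.samples.size
    n_new = int(round(n * factor))
    old_t = np.arange(n)
    new_t = np.arange(n_new) / factor
    new_t = np.clip(new_t, 0, n - 1)
    samples = np.interp(new_t, old_t, trace.samples)
    return Trace(samples, trace.sampling_rate * factor, trace.units,
                 trace.polarity, trace.name)
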