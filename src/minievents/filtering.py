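"""Shared smoothing helpers for detection and quantification."""

from __future__ import annotations

import numpy as np

__all__ = ["smooth_hann", "hann_points_for_rate"]


def smooth_hann(x: np.ndarray, n_points: int) -> np.ndarray:
    """Convolve with a normalized Hann window (identity for n_points <= 1)."""
    if n_points <= 1:
        return np.asarray(x, dtype=np.float64).copy()
    w = np.hanning(n_points + 2)[1:-1]  # drop the zero endpoints
    w /= w.sum()
    return np.convolve(x, w, mode="same")


def hann_points_for_rate(sampling_rate: float, base_points: int = 20,
                         base_rate: float = 50_000.0) -> int:
    """Filter length scaled with the sampling rate (20 points at 50 kHz)."""
    return max(1, int(round(base_points * sampling_rate / base_rate)))
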