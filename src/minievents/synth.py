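"""Synthetic ground-truth generation: biexponential events, noise traces,
event placement and labeled training windows."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _signal

from .trace import Trace

__all__ = [
    "SyntheticEventSpec", "GroundTruth", "biexp_kernel", "biexp_peak_time",
    "synth_noise", "place_events", "snr_db", "make_training_set",
    "make_benchmark_trace",
]


@dataclass(frozen=True)
class SyntheticEventSpec:
    """Statistical description of a population of synthetic events.

    ``amp_sigma`` is the spread parameter of the log-normal amplitude law.
    By default it is taken as the standard deviation of the underlying
    normal; set ``amp_sigma_is_variance`` to treat it as the variance.
    """

    tau_rise_ms: float = 0.2
    tau_decay_mean_ms: float = 1.0
    tau_decay_sd_ms: float = 0.25
    mean_amplitude: float = 10.0
    amp_sigma: float = 0.4
    amp_sigma_is_variance: bool = False
    frequency_hz: float = 0.7
    min_spacing_ms: float = 3.0
    polarity: str = "negative"

    def __post_init__(self):
        if self.tau_rise_ms <= 0 or self.tau_decay_mean_ms <= 0:
            raise ValueError("time constants must be positive")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        if self.min_spacing_ms < 0:
            raise ValueError("min_spacing must be non-negative")

    @property
    def log_sigma(self) -> float:
        return (np.sqrt(self.amp_sigma) if self.amp_sigma_is_variance
                else self.amp_sigma)

    def sign(self) -> int:
        return 1 if self.polarity == "positive" else -1


@dataclass
class GroundTruth:
    """True onsets and per-event parameters of a synthetic trace."""

    onset_times: np.ndarray  # seconds, sorted
    amplitudes: np.ndarray   # signal units, signed
    decay_taus: np.ndarray   # ms

    def __post_init__(self):
        self.onset_times = np.asarray(self.onset_times, dtype=np.float64)
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        self.decay_taus = np.asarray(self.decay_taus, dtype=np.float64)
        if not np.all(np.diff(self.onset_times) >= 0):
            raise ValueError("onset_times must be sorted")

    def __len__(self) -> int:
        return self.onset_times.size


def biexp_peak_time(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Closed-form argmax of (1 - exp(-t/tr)) * exp(-t/td), in ms."""
    return tau_rise_ms * np.log1p(tau_decay_ms / tau_rise_ms)


def biexp_kernel(tau_rise_ms: float, tau_decay_ms: float, dt_ms: float,
                 duration_ms: float, normalize: bool = True) -> np.ndarray:
    """Sample I(t) = (1 - exp(-t/tau_rise)) * exp(-t/tau_decay) on a grid.

    With ``normalize`` the waveform is divided by its analytic peak value
    so the maximum equals one (up to grid quantization).
    """
    if min(tau_rise_ms, tau_decay_ms, dt_ms) <= 0:
        raise ValueError("tau_rise, tau_decay and dt must be positive")
    t = np.arange(0.0, duration_ms, dt_ms)
    if duration_ms < biexp_peak_time(tau_rise_ms, tau_decay_ms):
        import warnings
        warnings.warn("kernel duration is shorter than the waveform peak time",
                      stacklevel=2)
    w = (1.0 - np.exp(-t / tau_rise_ms)) * np.exp(-t / tau_decay_ms)
    if normalize:
        tp = biexp_peak_time(tau_rise_ms, tau_decay_ms)
        peak = (1.0 - np.exp(-tp / tau_rise_ms)) * np.exp(-tp / tau_decay_ms)
        w = w / peak
    return w


def synth_noise(n: int, sampling_rate: float, sd: float, seed=None,
                model: str = "white", units: str = "pA",
                cutoff_hz: float | None = None) -> Trace:
    """Zero-mean Gaussian noise, optionally low-pass shaped.

    ``model='filtered'`` applies a 4-pole Butterworth low-pass (default
    cutoff: sampling_rate / 10) and rescales back to the requested SD,
    imitating amplifier filtering.
    """
    if sd < 0:
        raise ValueError("noise SD must be non-negative")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n) * sd
    if model == "filtered" and sd > 0:
        cutoff = cutoff_hz if cutoff_hz is not None else sampling_rate / 10
        sos = _signal.butter(4, cutoff, fs=sampling_rate, output="sos")
        x = _signal.sosfiltfilt(sos, x)
        x *= sd / x.std()
    elif model not in ("white", "filtered"):
        raise ValueError(f"unknown noise model '{model}'")
    return Trace(x, sampling_rate, units=units)


def _draw_onsets(rng, duration_s: float, frequency_hz: float,
                 min_spacing_s: float) -> np.ndarray:
    """Poisson event count, onsets uniform subject to a minimum spacing.

    Uses the exact construction: n uniform points in the interval shrunk
    by (n - 1) spacings, sorted, then shifted apart by the spacing.
    """
    n = rng.poisson(frequency_hz * duration_s)
    if n == 0:
        return np.empty(0)
    slack = duration_s - (n - 1) * min_spacing_s
    if slack <= 0:
        raise ValueError(
            f"cannot place {n} events with {min_spacing_s * 1e3:.1f} ms "
            f"spacing in {duration_s:.1f} s; reduce the event frequency")
    onsets = np.sort(rng.uniform(0, slack, size=n))
    return onsets + np.arange(n) * min_spacing_s


def _draw_amplitudes(rng, spec: SyntheticEventSpec, n: int) -> np.ndarray:
    """Log-normal magnitudes with mean ``spec.mean_amplitude``."""
    sigma = spec.log_sigma
    mu = np.log(spec.mean_amplitude) - 0.5 * sigma ** 2
    return rng.lognormal(mu, sigma, size=n)


def _draw_decay_taus(rng, spec: SyntheticEventSpec, n: int) -> np.ndarray:
    taus = rng.normal(spec.tau_decay_mean_ms, spec.tau_decay_sd_ms, size=n)
    while np.any(taus <= 0):  # resample non-physical draws
        bad = taus <= 0
        taus[bad] = rng.normal(spec.tau_decay_mean_ms, spec.tau_decay_sd_ms,
                               size=int(bad.sum()))
    return taus


def _add_event(samples: np.ndarray, onset_idx: int, amplitude: float,
               tau_rise_ms: float, tau_decay_ms: float,
               sampling_rate: float) -> None:
    dt_ms = 1e3 / sampling_rate
    duration_ms = max(10.0 * tau_decay_ms, 5 * dt_ms)
    kern = biexp_kernel(tau_rise_ms, tau_decay_ms, dt_ms, duration_ms,
                        normalize=True)
    end = min(onset_idx + kern.size, samples.size)
    samples[onset_idx:end] += amplitude * kern[:end - onset_idx]


def place_events(noise: Trace, spec: SyntheticEventSpec, seed=None
                 ) -> tuple[Trace, GroundTruth]:
    """Superimpose randomly placed biexponential events on a noise trace."""
    rng = np.random.default_rng(seed)
    duration = noise.duration
    onsets = _draw_onsets(rng, duration, spec.frequency_hz,
                          spec.min_spacing_ms / 1e3)
    n = onsets.size
    if spec.mean_amplitude == 0:
        amps = np.zeros(n)
    else:
        amps = _draw_amplitudes(rng, spec, n) * spec.sign()
    taus = _draw_decay_taus(rng, spec, n)
    samples = noise.samples.copy()
    idx = np.round(onsets * noise.sampling_rate).astype(int)
    for i, a, tau in zip(idx, amps, taus):
        if a != 0:
            _add_event(samples, i, a, spec.tau_rise_ms, tau,
                       noise.sampling_rate)
    trace = Trace(samples, noise.sampling_rate, units=noise.units,
                  polarity=spec.polarity)
    return trace, GroundTruth(onsets, amps, taus)


def snr_db(mean_amplitude: float, noise_sd: float) -> float:
    """SNR in dB: 20 * log10(mean event amplitude / noise SD)."""
    if noise_sd <= 0:
        raise ValueError("noise SD must be positive")
    if mean_amplitude <= 0:
        raise ValueError("mean amplitude must be positive (use magnitude)")
    return 20.0 * np.log10(mean_amplitude / noise_sd)


def amplitude_for_snr(snr_db_value: float, noise_sd: float) -> float:
    """Mean event amplitude giving the requested SNR against a noise SD."""
    return noise_sd * 10.0 ** (snr_db_value / 20.0)


def minmax_scale(windows: np.ndarray) -> np.ndarray:
    """Scale each row to [0, 1]; constant rows map to all zeros."""
    windows = np.atleast_2d(np.asarray(windows, dtype=np.float64))
    lo = windows.min(axis=1, keepdims=True)
    hi = windows.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] == 0
    span[flat] = 1.0
    out = (windows - lo) / span
    out[flat] = 0.0
    return out


def _artifact_window(rng, n: int, sampling_rate: float, sd: float
                     ) -> np.ndarray:
    """A typical false-positive waveform: either a step-like fast transient
    or a slow wave with symmetric rise and decay."""
    t = np.arange(n) / sampling_rate
    amp = sd * rng.uniform(3, 10) * rng.choice([-1.0, 1.0])
    if rng.random() < 0.5:
        # rapid transient: near-instant step with fast exponential return
        onset = rng.integers(n // 10, 9 * n // 10)
        tau = rng.uniform(0.5, 2) * (n / sampling_rate) / 50
        w = np.zeros(n)
        tt = t[: n - onset]
        w[onset:] = amp * np.exp(-tt / tau)
        return w
    # slow symmetric wave (Gaussian bump spanning much of the window)
    center = rng.uniform(0.3, 0.7) * t[-1]
    width = rng.uniform(0.15, 0.35) * t[-1]
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def make_training_set(spec: SyntheticEventSpec, n_pos: int, n_neg: int,
                      noise_sd: float = 1.0, window_len: int = 600,
                      sampling_rate: float = 50_000.0, augment: bool = True,
                      augment_fraction: float = 0.3,
                      noise_model: str = "white",
                      amplitude_range: tuple[float, float] | None = None,
                      seed=None):
    """Build labeled, min-max scaled windows for classifier training.

    Positives contain a single event at a jittered position; negatives are
    noise, a fraction of which carries non-event artifact waveforms when
    ``augment`` is on.  ``noise_model`` should match the recordings the
    classifier will be applied to ('white' or 'filtered').  When
    ``amplitude_range`` is given, event magnitudes are drawn log-uniform
    over that range (times ``noise_sd``) instead of from the spec's
    log-normal law, exposing the classifier to a broad band of
    signal-to-noise ratios.
    """
    from .nn.training import TrainingSet

    if n_pos < 0 or n_neg < 0:
        raise ValueError("window counts must be non-negative")
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    if noise_model == "white":
        windows = rng.standard_normal((n, window_len)) * noise_sd
    else:
        # cut windows from one long shaped-noise trace
        long = synth_noise(n * window_len, sampling_rate, noise_sd,
                           seed=rng, model=noise_model)
        windows = long.samples.reshape(n, window_len).copy()
    labels = np.zeros(n, dtype=np.int8)
    labels[:n_pos] = 1

    if amplitude_range is not None:
        lo, hi = amplitude_range
        amps = noise_sd * np.exp(rng.uniform(np.log(lo), np.log(hi),
                                             size=n_pos)) * spec.sign()
    else:
        amps = _draw_amplitudes(rng, spec, n_pos) * spec.sign()
    taus = _draw_decay_taus(rng, spec, n_pos)
    # leave room for the rising phase and part of the decay
    lo, hi = int(0.1 * window_len), int(0.7 * window_len)
    onsets = rng.integers(lo, hi, size=n_pos)
    for k in range(n_pos):
        _add_event(windows[k], onsets[k], amps[k], spec.tau_rise_ms,
                   taus[k], sampling_rate)
    if augment and n_neg:
        n_art = int(round(augment_fraction * n_neg))
        for k in rng.choice(np.arange(n_pos, n), size=n_art, replace=False):
            windows[k] += _artifact_window(rng, window_len, sampling_rate,
                                           noise_sd)
    perm = rng.permutation(n)
    return TrainingSet(minmax_scale(windows[perm]), labels[perm])


def make_benchmark_trace(duration_s: float = 30.0,
                         sampling_rate: float = 50_000.0,
                         snr: float = 12.0, noise_sd: float = 1.0,
                         spec: SyntheticEventSpec | None = None,
                         noise_model: str = "filtered", seed=None
                         ) -> tuple[Trace, GroundTruth]:
    """Convenience wrapper: noise trace + placed events at a target SNR (dB)."""
    spec = spec or SyntheticEventSpec()
    spec = replace(spec, mean_amplitude=amplitude_for_snr(snr, noise_sd))
    rng = np.random.default_rng(seed)
    noise = synth_noise(int(round(duration_s * sampling_rate)), sampling_rate,
                        noise_sd, seed=rng, model=noise_model)
    return place_events(noise, spec, seed=rng)
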