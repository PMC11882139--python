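"""Synthetic data generation and benchmark scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment, minimize_scalar

from minievents.benchmark import (detection_metrics, match_to_truth,
                                  threshold_sweep)
from minievents.synth import (GroundTruth, SyntheticEventSpec, biexp_kernel,
                              biexp_peak_time, make_benchmark_trace,
                              make_training_set, place_events, snr_db,
                              synth_noise)

# ---------------------------------------------------------------------------
# biexponential kernel
# ---------------------------------------------------------------------------

def test_kernel_starts_at_zero():
    w = biexp_kernel(0.3, 1.5, 0.02, 10.0, normalize=False)
    assert w[0] == 0.0


def test_peak_time_matches_numeric_maximization():
    tr, td = 0.1, 1.0
    t_closed = biexp_peak_time(tr, td)
    res = minimize_scalar(
        lambda t: -(1 - np.exp(-t / tr)) * np.exp(-t / td),
        bounds=(1e-6, 10.0), method="bounded")
    assert t_closed == pytest.approx(0.2398, abs=1e-4)
    assert t_closed == pytest.approx(res.x, abs=1e-5)


def test_normalized_kernel_peaks_at_one():
    dt = 0.001
    w = biexp_kernel(0.2, 1.0, dt, 10.0, normalize=True)
    t_star = biexp_peak_time(0.2, 1.0)
    assert w.max() == pytest.approx(1.0, abs=1e-5)
    assert abs(np.argmax(w) * dt - t_star) <= dt


def test_kernel_rejects_bad_taus():
    with pytest.raises(ValueError):
        biexp_kernel(-1.0, 1.0, 0.02, 5.0)


def test_kernel_warns_when_truncated_before_peak():
    with pytest.warns(UserWarning, match="peak"):
        biexp_kernel(1.0, 50.0, 0.5, 1.0)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def test_zero_sd_noise_is_all_zeros():
    tr = synth_noise(1000, 10_000.0, 0.0, seed=0)
    assert np.all(tr.samples == 0)


def test_noise_sd_converges():
    tr = synth_noise(10 ** 6, 50_000.0, 1.0, seed=1)
    assert 0.995 <= tr.samples.std() <= 1.005
    assert abs(tr.samples.mean()) < 0.005


def test_filtered_noise_matches_requested_sd_and_is_smoother():
    white = synth_noise(10 ** 5, 50_000.0, 1.0, seed=2, model="white")
    filt = synth_noise(10 ** 5, 50_000.0, 1.0, seed=2, model="filtered")
    assert filt.samples.std() == pytest.approx(1.0, rel=0.05)
    assert np.diff(filt.samples).std() < np.diff(white.samples).std()


def test_noise_is_seed_reproducible():
    a = synth_noise(1000, 10_000.0, 2.0, seed=42)
    b = synth_noise(1000, 10_000.0, 2.0, seed=42)
    np.testing.assert_array_equal(a.samples, b.samples)


def test_negative_sd_rejected():
    with pytest.raises(ValueError):
        synth_noise(10, 1000.0, -1.0)


# ---------------------------------------------------------------------------
# event placement
# ---------------------------------------------------------------------------

def test_mean_event_count_matches_rate():
    counts = []
    for seed in range(100):
        noise = synth_noise(120_000, 1000.0, 0.0, seed=seed)
        _, gt = place_events(noise, SyntheticEventSpec(), seed=seed)
        counts.append(len(gt))
    expectation = 0.7 * 120
    # Poisson SE over 100 seeds: sqrt(84/100) ~ 0.92
    assert np.mean(counts) == pytest.approx(expectation, abs=3.0)


def test_min_spacing_respected():
    noise = synth_noise(200_000, 10_000.0, 1.0, seed=3)
    spec = SyntheticEventSpec(frequency_hz=20.0, min_spacing_ms=3.0)
    _, gt = place_events(noise, spec, seed=3)
    assert len(gt) > 10
    assert np.diff(gt.onset_times).min() >= 3e-3


def test_zero_amplitude_leaves_noise_untouched():
    noise = synth_noise(50_000, 10_000.0, 1.0, seed=4)
    spec = SyntheticEventSpec(mean_amplitude=0.0)
    trace, _ = place_events(noise, spec, seed=4)
    np.testing.assert_array_equal(trace.samples, noise.samples)


def test_impossible_density_rejected():
    noise = synth_noise(1000, 1000.0, 0.0, seed=5)  # 1 s
    spec = SyntheticEventSpec(frequency_hz=600.0, min_spacing_ms=3.0)
    with pytest.raises(ValueError):
        place_events(noise, spec, seed=5)


def test_amplitude_law_moments():
    """Sample mean/median vs. the log-normal's analytic values (3 SE)."""
    spec = SyntheticEventSpec(mean_amplitude=10.0, amp_sigma=0.4)
    rng = np.random.default_rng(6)
    from minievents.synth import _draw_amplitudes
    n = 10_000
    amps = _draw_amplitudes(rng, spec, n)
    sigma = 0.4
    mu = np.log(10.0) - sigma ** 2 / 2
    an_mean = 10.0
    an_median = np.exp(mu)
    an_sd = an_mean * np.sqrt(np.exp(sigma ** 2) - 1)
    assert amps.mean() == pytest.approx(an_mean, abs=3 * an_sd / np.sqrt(n))
    assert np.median(amps) == pytest.approx(an_median, rel=0.03)


def test_amp_sigma_variance_interpretation():
    a = SyntheticEventSpec(amp_sigma=0.4, amp_sigma_is_variance=False)
    b = SyntheticEventSpec(amp_sigma=0.4, amp_sigma_is_variance=True)
    assert a.log_sigma == pytest.approx(0.4)
    assert b.log_sigma == pytest.approx(np.sqrt(0.4))


def test_decay_taus_positive_and_near_mean():
    noise = synth_noise(500_000, 10_000.0, 0.0, seed=7)
    spec = SyntheticEventSpec(frequency_hz=4.0)
    _, gt = place_events(noise, spec, seed=7)
    assert np.all(gt.decay_taus > 0)
    assert np.mean(gt.decay_taus) == pytest.approx(1.0, abs=0.15)


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ratio,expected", [(1.0, 0.0), (10.0, 20.0)])
def test_snr_db_conventions(ratio, expected):
    assert snr_db(ratio, 1.0) == pytest.approx(expected)


def test_snr_db_derived_value():
    assert snr_db(2.82, 1.0) == pytest.approx(9.0, abs=0.05)


def test_snr_db_rejects_nonpositive():
    with pytest.raises(ValueError):
        snr_db(-1.0, 1.0)
    with pytest.raises(ValueError):
        snr_db(1.0, 0.0)


# ---------------------------------------------------------------------------
# training set builder
# ---------------------------------------------------------------------------

def test_training_set_counts_and_balance():
    data = make_training_set(SyntheticEventSpec(), 1000, 1000, window_len=100,
                             sampling_rate=10_000.0, seed=8)
    assert len(data) == 2000
    assert data.labels.mean() == pytest.approx(0.5)
    assert 0.4 <= data.positive_fraction <= 0.6


def test_training_windows_scaled():
    data = make_training_set(SyntheticEventSpec(), 50, 50, window_len=100,
                             sampling_rate=10_000.0, seed=9)
    assert data.windows.min() >= 0.0
    assert data.windows.max() <= 1.0


def test_unaugmented_negatives_are_pure_noise():
    """No deterministic component: cross-correlation of negatives with the
    event kernel stays within a permutation-derived chance band."""
    spec = SyntheticEventSpec()
    data = make_training_set(spec, 0, 400, window_len=200,
                             sampling_rate=50_000.0, augment=False, seed=10)
    kern = biexp_kernel(spec.tau_rise_ms, spec.tau_decay_mean_ms, 0.02, 3.0)
    kern = (kern - kern.mean()) / kern.std()
    rng = np.random.default_rng(11)

    def max_corr(windows):
        c = np.abs(np.array([
            np.correlate(w - w.mean(), kern, mode="valid") for w in windows]))
        return c.max(axis=1).mean()

    observed = max_corr(data.windows)
    perms = [max_corr(rng.permuted(data.windows, axis=1))
             for _ in range(20)]
    assert observed <= np.mean(perms) + 3 * np.std(perms)


# ---------------------------------------------------------------------------
# matching and metrics
# ---------------------------------------------------------------------------

def _gt(times_s):
    t = np.sort(np.asarray(times_s, dtype=float))
    return GroundTruth(t, np.full(t.size, -10.0), np.full(t.size, 1.0))


def test_match_simple_case():
    truth = _gt([0.100, 0.200])
    assert match_to_truth([0.101, 0.500], truth, 5.0) == (1, 1, 1)


def test_match_perfect():
    truth = _gt(np.arange(10) * 0.1 + 0.05)
    assert match_to_truth(truth.onset_times, truth, 2.0) == (10, 0, 0)


def test_match_one_to_one_rule():
    truth = _gt([0.100])
    assert match_to_truth([0.0995, 0.1005], truth, 2.0) == (1, 1, 0)


def test_match_empty_inputs():
    truth = _gt([0.1, 0.2])
    assert match_to_truth([], truth, 2.0) == (0, 0, 2)
    assert match_to_truth([0.1, 0.2], _gt([]), 2.0) == (0, 2, 0)


def oracle_confusion(det, tru, tol_s):
    """Independent oracle: maximum bipartite matching within tolerance via
    the Hungarian algorithm on a padded cost matrix."""
    det, tru = np.asarray(det, float), np.asarray(tru, float)
    if det.size == 0 or tru.size == 0:
        return 0, det.size, tru.size
    big = 1e6
    cost = np.abs(det[:, None] - tru[None, :])
    cost = np.where(cost <= tol_s, cost, big)
    r, c = linear_sum_assignment(cost)
    tp = int(np.sum(cost[r, c] < big))
    return tp, det.size - tp, tru.size - tp


def test_greedy_matching_agrees_with_assignment_oracle():
    """100 random instances of <= 20 events; truth spacing exceeds twice
    the tolerance, as in the generated benchmark traces."""
    rng = np.random.default_rng(12)
    tol_ms = 2.0
    for _ in range(100):
        n_t = rng.integers(0, 21)
        truth = np.cumsum(rng.uniform(3 * tol_ms / 1e3, 0.1, size=n_t))
        n_keep = rng.integers(0, n_t + 1) if n_t else 0
        kept = rng.choice(truth, size=n_keep, replace=False) if n_keep else \
            np.empty(0)
        jitter = rng.uniform(-tol_ms / 2e3, tol_ms / 2e3, size=kept.size)
        fps = rng.uniform(0, 2.0, size=rng.integers(0, 6))
        det = np.sort(np.concatenate([kept + jitter, fps]))
        got = match_to_truth(det, _gt(truth) if n_t else _gt([]), tol_ms)
        assert got == oracle_confusion(det, truth, tol_ms / 1e3)


@pytest.mark.parametrize("tp,fp,fn,p,r,f1", [
    (10, 0, 0, 1.0, 1.0, 1.0),
    (8, 2, 2, 0.8, 0.8, 0.8),
    (0, 3, 3, 0.0, 0.0, 0.0),
])
def test_detection_metrics_examples(tp, fp, fn, p, r, f1):
    m = detection_metrics(tp, fp, fn)
    assert (m.precision, m.recall, m.f1) == \
        (pytest.approx(p), pytest.approx(r), pytest.approx(f1))


def test_detection_metrics_all_zero_convention():
    m = detection_metrics(0, 0, 0)
    assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)


@given(tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50))
@settings(max_examples=200, deadline=None)
def test_detection_metrics_formulas_property(tp, fp, fn):
    m = detection_metrics(tp, fp, fn)
    assert 0 <= m.precision <= 1 and 0 <= m.recall <= 1 and 0 <= m.f1 <= 1
    if tp + fp:
        assert m.precision == pytest.approx(tp / (tp + fp))
    if tp + fn:
        assert m.recall == pytest.approx(tp / (tp + fn))
    if m.precision + m.recall:
        assert m.f1 == pytest.approx(
            2 * m.precision * m.recall / (m.precision + m.recall))


def test_metrics_reject_negative_counts():
    with pytest.raises(ValueError):
        detection_metrics(-1, 0, 0)


# ---------------------------------------------------------------------------
# threshold sweep plumbing
# ---------------------------------------------------------------------------

class _StubDetector:
    """Threshold-crossing detector on a fixed criterion sequence."""

    default_threshold = -4.0

    def __init__(self, criterion, times):
        self.criterion = np.asarray(criterion, float)
        self.times = np.asarray(times, float)

    def detect(self, trace, threshold=None):
        thr = self.default_threshold if threshold is None else threshold
        return self.times[self.criterion <= thr]


def test_sweep_fraction_100_reproduces_default():
    crit = np.array([-10.0, -5.0, -3.0, -8.0])
    times = np.array([0.1, 0.2, 0.3, 0.4])
    det = _StubDetector(crit, times)
    truth = _gt([0.1, 0.2, 0.4])
    rows = threshold_sweep(det, trace=None, truth=truth,
                           fractions=[50, 100, 150])
    row100 = next(r for r in rows if r["fraction"] == 100)
    assert row100["n_detected"] == len(det.detect(None))


def test_sweep_counts_monotone_for_threshold_detector():
    rng = np.random.default_rng(13)
    crit = -rng.exponential(2.0, size=200)
    times = np.sort(rng.uniform(0, 10, size=200))
    det = _StubDetector(crit, times)
    rows = threshold_sweep(det, trace=None, truth=_gt([5.0]),
                           fractions=np.arange(5, 196, 10))
    counts = [r["n_detected"] for r in rows]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    assert counts[0] > counts[-1]


def test_sweep_isolates_row_errors():
    class Flaky(_StubDetector):
        def detect(self, trace, threshold=None):
            if threshold is not None and threshold > -2:
                raise RuntimeError("boom")
            return super().detect(trace, threshold)

    det = Flaky(np.array([-10.0]), np.array([0.1]))
    rows = threshold_sweep(det, trace=None, truth=_gt([0.1]),
                           fractions=[25, 100])
    assert "error" in rows[0]
    assert rows[1]["n_detected"] == 1


def test_benchmark_trace_reaches_target_snr():
    spec = SyntheticEventSpec(frequency_hz=10.0, min_spacing_ms=5.0)
    trace, gt = make_benchmark_trace(duration_s=5.0, sampling_rate=10_000.0,
                                     snr=12.0, noise_sd=1.0, spec=spec,
                                     seed=14)
    ratio = np.abs(gt.amplitudes).mean()
    assert snr_db(ratio, 1.0) == pytest.approx(12.0, abs=1.5)
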