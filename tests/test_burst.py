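"""Burst-detection chain on synthetic ground-truth rasters."""

import numpy as np
import pytest

from thetanet.burst import (
    AnalysisParameters,
    BurstSet,
    SpikeHistogram,
    _is_unstable,
    burst_bin_width,
    burst_metrics,
    categorize,
    detect_bursts,
    peak_frequency,
    rate_trace,
    spike_histogram,
)
from thetanet.fixtures import (
    make_homogeneous_raster,
    make_packet_raster,
    make_sinusoidal_raster,
)
from thetanet.raster import SpikeRaster


class TraceResult:
    """Minimal stand-in for a simulation result in analysis tests."""

    def __init__(self, raster, mean_v=None, dt=1.0):
        self.raster = raster
        self.mean_v = rate_trace(raster, dt) if mean_v is None else mean_v
        self.dt = dt


def test_peak_frequency_pure_tone():
    dt = 1.0
    t = np.arange(0, 4000.0, dt)
    trace = np.sin(2 * np.pi * 8.0 * t / 1000.0)
    assert peak_frequency(trace, dt) == pytest.approx(8.0, abs=0.3)


def test_peak_frequency_constant_trace_is_undefined():
    assert peak_frequency(np.full(4000, -60.0), 1.0) is None


def test_peak_frequency_picks_larger_power_component():
    t = np.arange(0, 4000.0, 1.0)
    trace = (2.0 * np.sin(2 * np.pi * 4.0 * t / 1000.0)
             + 1.0 * np.sin(2 * np.pi * 9.0 * t / 1000.0))
    assert peak_frequency(trace, 1.0) == pytest.approx(4.0, abs=0.3)


def test_peak_frequency_rejects_short_trace():
    with pytest.raises(ValueError):
        peak_frequency(np.zeros(100), 1.0, transient=500.0)


def test_bin_width_endpoints_and_monotonicity():
    # published endpoints: ~23 ms at 3 Hz down to ~7 ms at 12 Hz
    assert abs(burst_bin_width(3.0) - 23) <= 2
    assert abs(burst_bin_width(12.0) - 7) <= 2
    widths = [burst_bin_width(f) for f in range(3, 13)]
    assert all(a >= b for a, b in zip(widths, widths[1:]))
    assert widths[0] == 22 and widths[-1] == 8
    with pytest.raises(ValueError):
        burst_bin_width(0.0)


def test_spike_histogram_conserves_counts():
    raster = make_homogeneous_raster(5.0, 100, 4000.0, seed=0)
    hist = spike_histogram(raster, 10.0, transient=500.0)
    n_post = np.count_nonzero((raster.times >= 500.0)
                              & (raster.times < hist.edges[-1]))
    assert hist.counts.sum() == n_post
    assert hist.normalized.max() == pytest.approx(1.0)


def test_spike_histogram_empty_raster():
    raster = SpikeRaster(np.zeros(0), np.zeros(0, int), 10, 4000.0)
    hist = spike_histogram(raster, 10.0)
    assert hist.counts.sum() == 0
    assert np.all(hist.normalized == 0.0)


def test_histogram_peaks_follow_packet_period():
    raster = make_packet_raster(8.0, 100, 200, 4000.0, jitter=2.0, seed=1)
    hist = spike_histogram(raster, burst_bin_width(8.0), transient=500.0)
    peak_times = hist.centers[hist.normalized > 0.4]
    # clusters of high bins must be spaced by (a multiple of) ~125 ms
    gaps = np.diff(peak_times)
    gaps = gaps[gaps > 50.0]
    assert gaps.size > 10
    assert np.all(np.abs((gaps + 62.5) % 125.0 - 62.5) < 30.0)


def test_detect_bursts_counts_sinusoidal_rhythm():
    # population counts comparable to the reference-scale networks the
    # histogram normalization assumes (hundreds of spikes per bin)
    raster = make_sinusoidal_raster(8.0, 20.0, 1.0, 1000, 4000.0, seed=2)
    hist = spike_histogram(raster, burst_bin_width(8.0))
    bursts = detect_bursts(hist, 8.0)
    assert abs(bursts.n_bursts - 8.0 * 3.5) <= 2


def test_detect_bursts_rejects_homogeneous_firing():
    raster = make_homogeneous_raster(50.0, 1000, 4000.0, seed=3)
    hist = spike_histogram(raster, 10.0)
    bursts = detect_bursts(hist, 8.0)
    assert bursts.n_bursts <= 2


def test_detect_bursts_empty_histogram():
    hist = SpikeHistogram(edges=np.arange(0.0, 100.0, 10.0),
                          counts=np.zeros(9, int), normalized=np.zeros(9))
    assert detect_bursts(hist, 8.0).n_bursts == 0


def test_burst_count_scales_with_duration():
    counts = {}
    for dur in (4000.0, 8000.0):
        raster = make_sinusoidal_raster(6.0, 20.0, 1.0, 500, dur, seed=4)
        hist = spike_histogram(raster, burst_bin_width(6.0))
        counts[dur] = detect_bursts(hist, 6.0).n_bursts
    ratio = counts[8000.0] / counts[4000.0]
    assert ratio == pytest.approx((8.0 - 0.5) / (4.0 - 0.5), rel=0.15)


def test_burst_metrics_recover_packet_participation():
    raster = make_packet_raster(8.0, 100, 300, 4000.0, jitter=2.0, seed=5)
    hist = spike_histogram(raster, burst_bin_width(8.0))
    bursts = detect_bursts(hist, 8.0)
    metrics = burst_metrics(raster, bursts)
    assert len(metrics) > 10
    # boundaries sit between packets, so each kept burst holds one packet
    assert metrics["active_cells"].median() == 100
    assert metrics["active_cells"].mean() == pytest.approx(100, abs=3)
    assert metrics["total_spikes"].mean() == pytest.approx(100, abs=3)
    assert np.all(metrics["width_ms"] > 0)


def test_burst_metrics_empty_burst_set():
    raster = make_homogeneous_raster(5.0, 10, 2000.0, seed=0)
    assert len(burst_metrics(raster, BurstSet.empty())) == 0


def test_frequency_estimates_agree_on_robust_bursts():
    """Spectral peak vs inverse inter-burst interval within 20%."""
    raster = make_sinusoidal_raster(7.0, 20.0, 1.0, 500, 6000.0, seed=6)
    trace = rate_trace(raster, 1.0)
    f_fft = peak_frequency(trace, 1.0)
    hist = spike_histogram(raster, burst_bin_width(f_fft))
    bursts = detect_bursts(hist, f_fft)
    f_ibi = 1000.0 / np.mean(np.diff(bursts.boundaries))
    assert abs(f_fft - f_ibi) / f_fft < 0.2


@pytest.mark.parametrize("seed", range(5))
def test_burst_detector_recall_and_precision(seed):
    """Recall and precision >= 0.9 on strongly modulated Poisson rasters."""
    f = 8.0
    raster = make_sinusoidal_raster(f, 20.0, 0.9, 1000, 4000.0, seed=seed)
    hist = spike_histogram(raster, burst_bin_width(f))
    bursts = detect_bursts(hist, f)
    # ground truth: one burst per modulation cycle, peaks at (k + 0.25)/f
    period = 1000.0 / f
    true_peaks = np.arange(0.25 * period, 4000.0, period)
    true_peaks = true_peaks[true_peaks >= 500.0 + period]
    hits = 0
    for t0, t1 in zip(bursts.starts, bursts.ends):
        if np.count_nonzero((true_peaks >= t0) & (true_peaks < t1)) == 1:
            hits += 1
    precision = hits / bursts.n_bursts
    matched = np.count_nonzero(
        [(np.count_nonzero((tp >= bursts.starts) & (tp < bursts.ends)) == 1)
         for tp in true_peaks])
    recall = matched / true_peaks.size
    assert precision >= 0.9
    assert recall >= 0.9


def test_instability_rule_requires_two_double_collapses():
    stable = np.array([1.0, 0.9, 1.0, 0.95, 0.9, 1.0])
    assert not _is_unstable(stable, 0.79)
    one_event = np.array([1.0, 0.1, 0.01, 1.0, 0.9])
    assert not _is_unstable(one_event, 0.79)
    two_events = np.array([1.0, 0.1, 0.01, 1.0, 0.1, 0.01, 1.0])
    assert _is_unstable(two_events, 0.79)


def test_categorize_empty_raster_is_nonfiring():
    raster = SpikeRaster(np.zeros(0), np.zeros(0, int), 100, 4000.0,
                         populations={"PYR": slice(0, 100)})
    cat = categorize(TraceResult(raster, mean_v=np.zeros(4001)))
    assert cat.label == "nonfiring"


def test_categorize_rhythmic_fixture_is_theta_stable():
    # 200 cells at 8 Hz modulation: well above the (scaled) nonfiring cut
    raster = make_sinusoidal_raster(8.0, 30.0, 1.0, 200, 4000.0, seed=8)
    cat = categorize(TraceResult(raster))
    assert cat.label == "theta_stable"
    assert cat.f_peak == pytest.approx(8.0, abs=0.5)


def test_categorization_invariant_to_cell_permutation():
    raster = make_sinusoidal_raster(8.0, 30.0, 1.0, 200, 4000.0, seed=9)
    rng = np.random.default_rng(0)
    perm = rng.permutation(raster.n_cells)
    shuffled = SpikeRaster(raster.times.copy(), perm[raster.cells],
                           raster.n_cells, raster.duration,
                           populations=dict(raster.populations))
    a = categorize(TraceResult(raster))
    b = categorize(TraceResult(shuffled))
    assert a.label == b.label
    assert a.f_peak == b.f_peak
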