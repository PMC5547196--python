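"""Synthetic ground-truth inputs for validating the analysis chain.

These generators emulate the statistical structure the analysis assumes —
oscillatory population bursting in rasters and event-like postsynaptic
currents in traces — without any network simulation, so burst detection and
peak measurement can be tested against known truth.
"""

from __future__ import annotations


import numpy as np

from .network import NetworkSpec, pyr_pv_network, rescale_network
from .raster import SpikeRaster

__all__ = [
    "make_sinusoidal_raster",
    "make_homogeneous_raster",
    "make_packet_raster",
    "make_current_trace",
    "make_mini_network",
]


def make_sinusoidal_raster(
    f_mod: float,
    base_rate: float,
    depth: float,
    n_cells: int,
    duration: float,
    seed=None,
) -> SpikeRaster:
    """Inhomogeneous-Poisson raster with sinusoidal rate modulation.

    Each of ``n_cells`` cells spikes as an independent Poisson process with
    rate r(t) = base_rate * (1 + depth * sin(2 pi f_mod t)) (Hz), giving a
    known population-burst frequency ``f_mod``.  Implemented by thinning a
    homogeneous process at the rate ceiling.

    Parameters: f_mod in Hz, base_rate in Hz per cell, depth in [0, 1],
    duration in ms.
    """
    if not (0.0 <= depth <= 1.0):
        raise ValueError("depth must be in [0, 1]")
    if base_rate < 0 or f_mod <= 0:
        raise ValueError("rates and modulation frequency must be positive")
    rng = np.random.default_rng(seed)
    times_all, cells_all = [], []
    r_max = base_rate * (1.0 + depth)
    dur_s = duration / 1000.0
    for c in range(n_cells):
        n_cand = rng.poisson(r_max * dur_s)
        t = rng.uniform(0.0, duration, size=n_cand)
        rate = base_rate * (1.0 + depth * np.sin(2 * np.pi * f_mod * t / 1000.0))
        keep = rng.random(n_cand) * r_max < rate
        times_all.append(t[keep])
        cells_all.append(np.full(keep.sum(), c, np.int64))
    times = np.concatenate(times_all) if times_all else np.zeros(0)
    cells = np.concatenate(cells_all) if cells_all else np.zeros(0, np.int64)
    return SpikeRaster(times, cells, n_cells, duration,
                       populations={"PYR": slice(0, n_cells)})


def make_homogeneous_raster(base_rate: float, n_cells: int, duration: float,
                            seed=None) -> SpikeRaster:
    """Homogeneous-Poisson raster (no rhythm): depth-0 sinusoidal raster."""
    return make_sinusoidal_raster(1.0, base_rate, 0.0, n_cells, duration, seed)


def make_packet_raster(
    f_mod: float,
    k_active: int,
    n_cells: int,
    duration: float,
    jitter: float = 2.0,
    seed=None,
) -> SpikeRaster:
    """Raster of periodic spike packets with exact per-burst participation.

    Packets occur at period 1000/f_mod ms; in each packet exactly
    ``k_active`` cells (chosen per packet) fire once, at the packet time
    plus Gaussian jitter (ms).  Ground truth: active cells per burst equals
    ``k_active``; a jitter much larger than the period destroys the rhythm
    (negative control).
    """
    if k_active > n_cells:
        raise ValueError("k_active cannot exceed n_cells")
    rng = np.random.default_rng(seed)
    period = 1000.0 / f_mod
    packet_times = np.arange(period, duration - 0.5 * period, period)
    times_all, cells_all = [], []
    for tp in packet_times:
        chosen = rng.permutation(n_cells)[:k_active]
        t = tp + rng.normal(0.0, jitter, size=k_active)
        ok = (t > 0) & (t < duration)
        times_all.append(t[ok])
        cells_all.append(chosen[ok].astype(np.int64))
    times = np.concatenate(times_all) if times_all else np.zeros(0)
    cells = np.concatenate(cells_all) if cells_all else np.zeros(0, np.int64)
    return SpikeRaster(times, cells, n_cells, duration,
                       populations={"PYR": slice(0, n_cells)})


def make_current_trace(
    n_events: int,
    duration: float,
    record_dt: float = 0.2,
    amplitude_mean: float = 300.0,
    amplitude_sd: float = 30.0,
    decay_ms: float = 3.0,
    noise_sd: float = 0.0,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic PSC trace: exponential-decay events at random times.

    Events occur at uniform random times with Normal(amplitude_mean,
    amplitude_sd) amplitudes (pA) and single-exponential decay, on top of
    Gaussian noise.  Returns (trace, true_amplitudes); event times are
    spaced at least 5 decay constants apart so the true peak list is
    unambiguous.
    """
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration / record_dt))
    t = np.arange(n_samples) * record_dt
    trace = rng.normal(0.0, noise_sd, n_samples) if noise_sd > 0 else np.zeros(n_samples)
    if n_events == 0:
        return trace, np.zeros(0)
    gap = 5.0 * decay_ms
    lo, hi = 1100.0, duration - gap
    if hi <= lo or (hi - lo) < n_events * gap:
        raise ValueError("duration too short for the requested event count")
    event_times = np.sort(rng.uniform(lo, hi, n_events))
    while np.any(np.diff(event_times) < gap):
        event_times = np.sort(rng.uniform(lo, hi, n_events))
    amps = rng.normal(amplitude_mean, amplitude_sd, n_events)
    for t0, amp in zip(event_times, amps):
        mask = t >= t0
        trace[mask] += amp * np.exp(-(t[mask] - t0) / decay_ms)
    return trace, amps


def make_mini_network(scale: float, g_pyr: float = 0.014,
                      c_pyr_pv: float = 0.02, c_pv_pyr: float = 0.3,
                      **kwargs) -> NetworkSpec:
    """Reference excitatory-inhibitory circuit downscaled for fast tests.

    ``scale`` = 1 gives the default 10,000 PYR / 500 PV network; smaller
    values shrink every population with N*p*g-compensated conductances.
    """
    if not (0 < scale <= 1):
        raise ValueError("scale must be in (0, 1]")
    spec = pyr_pv_network(g_pyr=g_pyr, c_pyr_pv=c_pyr_pv, c_pv_pyr=c_pv_pyr,
                          **kwargs)
    if scale == 1:
        return spec
    return rescale_network(spec, scale, compensate="auto")
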