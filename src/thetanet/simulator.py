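"""Clock-driven network simulation.

Deterministic runs use forward Euler with dt = 0.02 ms; runs with the
fluctuating-conductance drive use explicit second-order Runge-Kutta (Heun)
with dt = 0.04 ms, with the OU conductance advanced once per step by its
exact transition outside the RK2 stages.  Initial membrane potentials are
uniform random in [-65, -55] mV; the recovery variable starts at 0 and all
gating variables at 0.

Three independent seed streams (connectivity, initial conditions, noise) are
spawned from a single master seed, so a run is reproducible bit-for-bit from
(network spec, drive spec, config).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from .cells import CellParameters, builtin_parameters
from .drive import DeterministicDriveSpec, OUDriveSpec, sample_tonic_drive
from .network import NetworkSpec
from .raster import SpikeRaster
from .synapses import (
    E_EXC,
    E_INH,
    PULSE_DURATION_MS,
    builtin_synapse_class,
)

__all__ = ["SimulationConfig", "SimulationResult", "initialize_state", "run",
           "compare_integrators"]

V_INIT_LOW = -65.0
V_INIT_HIGH = -55.0

DT_EULER = 0.02  # ms, deterministic runs
DT_RK2 = 0.04    # ms, noisy runs


@dataclass(frozen=True)
class SimulationConfig:
    """Integration, transient, seed, and recording settings for one run."""

    dt: float = DT_EULER
    duration: float = 10_000.0       # ms; excitatory-only runs default to 10 s
    integrator: str = "euler"        # "euler" or "rk2"
    transient_spikes: float = 500.0   # ms discarded by spike/spectral analysis
    transient_currents: float = 1000.0  # ms discarded by PSC-peak analysis
    seed: int = 0
    n_record_pyr: int = 100          # cells with EPSC/IPSC traces recorded
    n_record_pv: int = 50
    record_dt: float = 0.2           # ms between recorded current samples

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= self.transient_spikes:
            raise ValueError("duration must exceed the spike transient")
        if self.integrator not in ("euler", "rk2"):
            raise ValueError("integrator must be 'euler' or 'rk2'")

    def seed_streams(self) -> tuple[np.random.Generator, np.random.Generator, int]:
        """(connectivity rng, init rng, 32-bit noise seed for the kernel)."""
        ss = np.random.SeedSequence(self.seed)
        conn_ss, init_ss, noise_ss = ss.spawn(3)
        noise_seed = int(noise_ss.generate_state(1, np.uint32)[0])
        return (np.random.default_rng(conn_ss), np.random.default_rng(init_ss),
                noise_seed)


@dataclass
class SimulationResult:
    """Raster, population activity, recorded PSC traces, and the config echo."""

    raster: SpikeRaster
    mean_v: np.ndarray                 # overall population activity, (n_steps+1,)
    mean_v_pop: dict[str, np.ndarray]  # per-population mean V
    dt: float
    duration: float
    recorded_cells: dict[str, np.ndarray]  # population -> global cell indices
    epsc: np.ndarray                   # (n_samples, n_recorded) signed pA
    ipsc: np.ndarray
    record_columns: dict[str, slice]   # population -> columns of epsc/ipsc
    record_dt: float
    config: SimulationConfig
    network: NetworkSpec
    drive: object
    tonic_drive: np.ndarray | None = None   # per-cell constant currents (pA)

    @property
    def n_spikes(self) -> int:
        return self.raster.n_spikes


def initialize_state(
    network: NetworkSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Initial (V, u): V ~ Uniform(-65, -55) mV per cell, u = 0."""
    n = network.n_cells
    V = rng.uniform(V_INIT_LOW, V_INIT_HIGH, size=n)
    u = np.zeros(n)
    return V, u


def _cell_arrays(network: NetworkSpec,
                 overrides: dict[str, CellParameters] | None):
    fields = ("v_r", "v_t", "v_peak", "a", "b", "c", "d",
              "k_low", "k_high", "C_m", "I_shift")
    n = network.n_cells
    arrays = {f: np.empty(n) for f in fields}
    pop_id = np.empty(n, np.int64)
    for q, pop in enumerate(network.populations):
        sl = network.population_slices()[pop.name]
        p = (overrides or {}).get(pop.name) or builtin_parameters(pop.cell_label)
        for f in fields:
            arrays[f][sl] = getattr(p, f)
        pop_id[sl] = q
    return arrays, pop_id


def _build_csr(n_src: int, pre: np.ndarray, post_global: np.ndarray):
    """Row-sorted CSR over local source index; targets are global indices."""
    order = np.argsort(pre, kind="stable")
    pre = pre[order]
    targets = post_global[order]
    counts = np.bincount(pre, minlength=n_src)
    indptr = np.zeros(n_src + 1, np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, targets.astype(np.int64)


def run(
    network: NetworkSpec,
    drive,
    config: SimulationConfig,
    cell_overrides: dict[str, CellParameters] | None = None,
) -> SimulationResult:
    """Simulate one network run and return its complete result.

    ``drive`` is a DeterministicDriveSpec or an OUDriveSpec and is applied to
    the PYR population when one exists (otherwise to the first population);
    in excitatory-inhibitory networks the PV+ cells receive excitation only
    through the PYR->PV projection.
    """
    rng_conn, rng_init, noise_seed = config.seed_streams()
    slices = network.population_slices()
    n = network.n_cells
    n_steps = int(round(config.duration / config.dt))

    arrays, pop_id = _cell_arrays(network, cell_overrides)
    inv_Cm = 1.0 / arrays["C_m"]
    pop_size = np.array([p.size for p in network.populations], float)

    # --- connectivity (quenched; own stream)
    adjacency = network.sample_adjacency(rng_conn)
    src_start, n_src, gmax, is_exc = [], [], [], []
    e_on, e_off, s_inf_l, iptr_off, s_off = [], [], [], [], []
    flat_indptr_parts, flat_target_parts = [], []
    iptr_pos = 0
    s_pos = 0
    for proj, (pre, post) in zip(network.projections, adjacency):
        syn = builtin_synapse_class(proj.synapse_label)
        ns = network.population(proj.source).size
        indptr, targets = _build_csr(ns, pre, post + slices[proj.target].start)
        indptr = indptr + sum(len(tp) for tp in flat_target_parts)
        flat_indptr_parts.append(indptr)
        flat_target_parts.append(targets)
        src_start.append(slices[proj.source].start)
        n_src.append(ns)
        gmax.append(proj.g)
        is_exc.append(syn.E_rev == E_EXC)
        e_on.append(math.exp(-config.dt / syn.tau_s))
        e_off.append(math.exp(-syn.beta * config.dt))
        s_inf_l.append(syn.s_inf)
        iptr_off.append(iptr_pos)
        iptr_pos += ns + 1
        s_off.append(s_pos)
        s_pos += ns
    flat_indptr = (np.concatenate(flat_indptr_parts) if flat_indptr_parts
                   else np.zeros(0, np.int64))
    flat_targets = (np.concatenate(flat_target_parts) if flat_target_parts
                    else np.zeros(0, np.int64))
    flat_s = np.zeros(s_pos)

    # --- initial conditions and tonic drive (init stream)
    V, u = initialize_state(network, rng_init)
    drive_pop = "PYR" if "PYR" in slices else network.populations[0].name
    drive_sl = slices[drive_pop]
    I_tonic = np.zeros(n)
    ou_mask = np.zeros(n, np.bool_)
    ou_g = np.zeros(n)
    if isinstance(drive, DeterministicDriveSpec):
        I_tonic[drive_sl] = sample_tonic_drive(
            drive, drive_sl.stop - drive_sl.start, rng_init)
        ou_decay, ou_sd_eff, ou_mean, ou_erev = 1.0, -1.0, 0.0, E_EXC
    elif isinstance(drive, OUDriveSpec):
        ou_mask[drive_sl] = True
        ou_g[drive_sl] = drive.g_e_mean
        ou_decay = math.exp(-config.dt / drive.tau_e)
        ou_sd_eff = drive.sigma_e * math.sqrt(1.0 - ou_decay * ou_decay)
        ou_mean, ou_erev = drive.g_e_mean, drive.E_rev
    else:
        raise TypeError(f"unsupported drive spec {type(drive).__name__}")

    # --- recording plan: seeded permutation, first indices
    recorded_cells: dict[str, np.ndarray] = {}
    record_columns: dict[str, slice] = {}
    rec_parts = []
    col = 0
    for pop in network.populations:
        want = {"PYR": config.n_record_pyr, "PV": config.n_record_pv}.get(pop.name, 0)
        k = min(want, pop.size)
        if k == 0:
            continue
        sl = slices[pop.name]
        idx = np.sort(rng_init.permutation(pop.size)[:k]) + sl.start
        recorded_cells[pop.name] = idx
        record_columns[pop.name] = slice(col, col + k)
        rec_parts.append(idx)
        col += k
    rec_idx = (np.concatenate(rec_parts) if rec_parts else np.zeros(0, np.int64))
    rec_stride = max(1, int(round(config.record_dt / config.dt)))
    n_samples = (n_steps - 1) // rec_stride + 1 if n_steps else 0
    rec_exc = np.zeros((n_samples, rec_idx.size))
    rec_inh = np.zeros((n_samples, rec_idx.size))

    # --- outputs
    cap = int(n * (config.duration / 1000.0) * 300) + 10_000
    spike_t = np.empty(cap)
    spike_i = np.empty(cap, np.int64)
    mean_v = np.zeros((n_steps + 1, len(network.populations)))

    n_spk, status, err_step, err_cell = _kernel.network_kernel(
        config.dt, n_steps, 0 if config.integrator == "euler" else 1,
        arrays["v_r"], arrays["v_t"], arrays["v_peak"], arrays["a"],
        arrays["b"], arrays["c"], arrays["d"], arrays["k_low"],
        arrays["k_high"], inv_Cm, arrays["I_shift"],
        pop_id, len(network.populations), pop_size,
        V, u,
        I_tonic,
        ou_mask, ou_g, ou_mean, ou_decay, ou_sd_eff, ou_erev, noise_seed,
        np.array(src_start, np.int64), np.array(n_src, np.int64),
        np.array(gmax, float), np.array(is_exc, np.bool_),
        np.array(e_on, float), np.array(e_off, float), np.array(s_inf_l, float),
        np.array(iptr_off, np.int64), flat_indptr, flat_targets, flat_s,
        np.array(s_off, np.int64),
        np.full(n, -np.inf), PULSE_DURATION_MS,
        E_EXC, E_INH,
        rec_idx, rec_stride,
        spike_t, spike_i,
        mean_v, rec_exc, rec_inh,
    )
    if status == _kernel.STATUS_BLOWUP:
        raise RuntimeError(
            f"numerical blow-up (|V| > 1e3 mV) at step {err_step} "
            f"(t = {err_step * config.dt:.2f} ms), cell {err_cell}"
        )
    if status == _kernel.STATUS_SPIKE_OVERFLOW:
        raise RuntimeError(
            f"spike buffer overflow at step {err_step}; "
            "the network is firing far above physiological rates"
        )

    raster = SpikeRaster(
        times=spike_t[:n_spk].copy(),
        cells=spike_i[:n_spk].copy(),
        n_cells=n,
        duration=config.duration,
        populations=dict(slices),
    )
    overall = mean_v @ (pop_size / pop_size.sum())
    mean_v_pop = {
        pop.name: mean_v[:, q] for q, pop in enumerate(network.populations)
    }
    return SimulationResult(
        raster=raster,
        mean_v=overall,
        mean_v_pop=mean_v_pop,
        dt=config.dt,
        duration=config.duration,
        recorded_cells=recorded_cells,
        epsc=rec_exc,
        ipsc=rec_inh,
        record_columns=record_columns,
        record_dt=rec_stride * config.dt,
        config=config,
        network=network,
        drive=drive,
        tonic_drive=I_tonic if isinstance(drive, DeterministicDriveSpec) else None,
    )


def compare_integrators(
    network: NetworkSpec,
    drive,
    config: SimulationConfig,
    dt_euler: float = DT_EULER,
    dt_rk2: float = DT_RK2,
) -> dict:
    """Run the same configuration under Euler and Heun and report divergences.

    Seeds are shared, so connectivity and initial conditions are identical;
    with noisy drive the realized noise paths differ because the step counts
    differ, which is why this check targets deterministic drives.
    """
    from .burst import peak_frequency

    res_e = run(network, drive, replace(config, integrator="euler", dt=dt_euler))
    res_r = run(network, drive, replace(config, integrator="rk2", dt=dt_rk2))
    f_e = peak_frequency(res_e.mean_v, res_e.dt, config.transient_spikes)
    f_r = peak_frequency(res_r.mean_v, res_r.dt, config.transient_spikes)
    return {
        "f_peak_euler": f_e,
        "f_peak_rk2": f_r,
        "f_peak_difference": (abs(f_e - f_r)
                              if (f_e is not None and f_r is not None) else None),
        "spikes_euler": res_e.n_spikes,
        "spikes_rk2": res_r.n_spikes,
        "spike_count_difference": abs(res_e.n_spikes - res_r.n_spikes),
    }
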