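"""Clock-driven simulator: reproducibility, self-consistency, numerics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from thetanet.cells import CellParameters, builtin_parameters, f_i_curve
from thetanet.drive import DeterministicDriveSpec, OUDriveSpec
from thetanet.network import NetworkSpec, PopulationSpec, pyr_network
from thetanet.simulator import SimulationConfig, initialize_state, run


def single_pop_network(label: str, n: int, name: str | None = None) -> NetworkSpec:
    name = name or ("PV" if label == "PV" else "PYR")
    return NetworkSpec(populations=(PopulationSpec(name, n, label),),
                       projections=())


def test_initial_conditions_uniform_band_and_zero_recovery():
    net = pyr_network(g_pyr=0.0, n_pyr=500)
    V, u = initialize_state(net, np.random.default_rng(0))
    assert V.min() >= -65.0 and V.max() <= -55.0
    assert np.all(u == 0.0)
    V2, _ = initialize_state(net, np.random.default_rng(0))
    np.testing.assert_array_equal(V, V2)


def test_subthreshold_network_is_silent():
    """Weakly adapting cells at zero drive sit below rheobase: no spikes."""
    net = single_pop_network("weakly_adapting_PYR", 10)
    cfg = SimulationConfig(duration=1000.0, seed=0)
    res = run(net, DeterministicDriveSpec(I_app=0.0), cfg)
    assert res.n_spikes == 0
    assert res.raster.times.size == 0


def test_network_rate_matches_f_i_curve():
    """One isolated PV cell at 200 pA fires at its f-I rate (internal oracle)."""
    net = single_pop_network("PV", 1)
    cfg = SimulationConfig(duration=2000.0, seed=0)
    res = run(net, DeterministicDriveSpec(I_app=200.0), cfg)
    net_rate = res.n_spikes / (cfg.duration / 1000.0)
    fi_rate = f_i_curve(builtin_parameters("PV"), [200.0], duration=2000.0)[0]
    assert abs(net_rate - fi_rate) <= 1.0


def test_bit_identical_reproducibility():
    net = pyr_network(g_pyr=0.24, n_pyr=100)
    cfg = SimulationConfig(duration=1000.0, seed=123)
    a = run(net, DeterministicDriveSpec(I_app=65.0), cfg)
    b = run(net, DeterministicDriveSpec(I_app=65.0), cfg)
    np.testing.assert_array_equal(a.raster.times, b.raster.times)
    np.testing.assert_array_equal(a.raster.cells, b.raster.cells)
    np.testing.assert_array_equal(a.mean_v, b.mean_v)
    assert a.n_spikes > 0


def test_noisy_run_reproducible_and_seed_sensitive():
    net = pyr_network(g_pyr=0.24, n_pyr=50)
    cfg = SimulationConfig(duration=800.0, dt=0.04, integrator="rk2", seed=5)
    drive = OUDriveSpec(g_e_mean=1.0, sigma_e=0.6)
    a = run(net, drive, cfg)
    b = run(net, drive, cfg)
    np.testing.assert_array_equal(a.raster.times, b.raster.times)
    c = run(net, drive, SimulationConfig(duration=800.0, dt=0.04,
                                         integrator="rk2", seed=6))
    assert (a.raster.times.size != c.raster.times.size
            or not np.array_equal(a.raster.times, c.raster.times))


def test_trace_lengths_and_spike_time_range():
    net = pyr_network(g_pyr=0.0, n_pyr=20)
    cfg = SimulationConfig(duration=601.0, seed=1)
    res = run(net, DeterministicDriveSpec(I_app=80.0), cfg)
    n_steps = int(round(cfg.duration / cfg.dt))
    assert res.mean_v.shape == (n_steps + 1,)
    assert res.n_spikes > 0
    assert res.raster.times.min() > 0.0
    assert res.raster.times.max() <= cfg.duration
    assert np.all(np.diff(res.raster.times) >= 0)


def test_membrane_equation_matches_reference_integration():
    """With a negligible quadratic term the cell is linear; the kernel's
    subthreshold trajectory must match a high-accuracy ODE solution."""
    p = CellParameters("linear_test", v_r=-60.0, v_t=-59.999999, v_peak=0.0,
                       a=0.05, b=2.0, c=-65.0, d=0.0, k_low=1e-12,
                       k_high=1e-12, C_m=100.0, I_shift=0.0)
    net = NetworkSpec(populations=(PopulationSpec("PYR", 1, "PV"),),
                      projections=())
    I = 40.0

    def rhs(t, y):
        V, u = y
        return [(-u + I) / p.C_m, p.a * (p.b * (V - p.v_r) - u)]

    # Heun is second order: two orders tighter than forward Euler here
    for integrator, dt, rel in (("euler", 0.02, 1e-4), ("rk2", 0.04, 1e-6)):
        cfg = SimulationConfig(duration=600.0, dt=dt, integrator=integrator,
                               seed=2)
        res = run(net, DeterministicDriveSpec(I_app=I), cfg,
                  cell_overrides={"PYR": p})
        sol = solve_ivp(rhs, (0.0, cfg.duration), [res.mean_v[0], 0.0],
                        rtol=1e-12, atol=1e-13, dense_output=True)
        for t in (100.0, 300.0, 600.0):
            ref = sol.sol(t)[0]
            got = res.mean_v[int(round(t / cfg.dt))]
            assert got == pytest.approx(ref, rel=rel)


def test_blowup_aborts_with_diagnostic():
    p = CellParameters("runaway", v_r=-60.0, v_t=-50.0, v_peak=1e6,
                       a=0.0, b=0.0, c=-65.0, d=0.0, k_low=1.0, k_high=1.0,
                       C_m=1.0, I_shift=0.0)
    net = NetworkSpec(populations=(PopulationSpec("PYR", 1, "PV"),),
                      projections=())
    cfg = SimulationConfig(duration=600.0, seed=0)
    with pytest.raises(RuntimeError, match="blow-up.*cell 0"):
        run(net, DeterministicDriveSpec(I_app=500.0), cfg,
            cell_overrides={"PYR": p})


def test_recording_plan_sizes():
    net = pyr_network(g_pyr=0.24, n_pyr=120)
    cfg = SimulationConfig(duration=700.0, seed=4, n_record_pyr=10,
                           record_dt=0.2)
    res = run(net, DeterministicDriveSpec(I_app=65.0), cfg)
    assert res.recorded_cells["PYR"].size == 10
    assert res.epsc.shape[1] == 10
    assert res.record_dt == pytest.approx(0.2)
    n_samples = (int(round(700.0 / 0.02)) - 1) // 10 + 1
    assert res.epsc.shape[0] == n_samples


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(dt=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(duration=400.0)           # below the 500 ms transient
    with pytest.raises(ValueError):
        SimulationConfig(integrator="rk4")
    with pytest.raises(TypeError):
        run(pyr_network(g_pyr=0.0, n_pyr=1), object(), SimulationConfig(duration=600.0))


def test_tonic_drive_vector_echoed_for_audits():
    net = pyr_network(g_pyr=0.0, n_pyr=30)
    cfg = SimulationConfig(duration=600.0, seed=8)
    res = run(net, DeterministicDriveSpec(I_app=20.0, sigma_app=5.0), cfg)
    assert res.tonic_drive is not None and res.tonic_drive.shape == (30,)
    assert res.tonic_drive.std() > 0
    res2 = run(net, DeterministicDriveSpec(I_app=20.0, sigma_app=5.0), cfg)
    np.testing.assert_array_equal(res.tonic_drive, res2.tonic_drive)
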