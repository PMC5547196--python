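# thetanet

Spiking-network models of the **intrinsic CA1 theta rhythm**: how a
hippocampal microcircuit of ~10,000 excitatory pyramidal (PYR) cells and
~500 fast-firing parvalbumin-positive (PV+) interneurons generates 3–12 Hz
population bursts with *sparse* pyramidal firing, and which
excitatory/inhibitory balance regime is consistent with whole-hippocampus
recordings.

The package is for computational neuroscientists who want to simulate,
analyze, or extend these circuit models: it provides the cell and synapse
equations, a fast clock-driven simulator, the full burst-detection and
categorization chain, EPSC/IPSC peak analysis with Scenario A/B
classification, parameter-sweep orchestration, and synthetic ground-truth
generators for testing the analysis in isolation.

## Model

Cells follow an Izhikevich-type quadratic integrate-and-fire model with a
recovery current *u* producing spike-frequency adaptation (PYR) or
fast-firing dynamics (PV+):

```
C_m dV/dt = k (V − v_r)(V − v_t) − u + I_shift + I_other − I_syn
   du/dt = a [ b (V − v_r) − u ],      V ≥ v_peak  ⇒  V ← c, u ← u + d
```

Synapses are kinetic conductances, `I_syn = g s (V − E_rev)` with
`ds/dt = α[T](1−s) − βs` driven by 1 ms transmitter pulses
(AMPA: E_rev = −15 mV; GABA_A: −85 mV).  "Other" drive is either a
per-cell tonic current ~ N(I_app, σ_app²) or a fluctuating excitatory
conductance following an Ornstein–Uhlenbeck process (τ_e = 2.73 ms).
Networks are random (PYR→PYR p = 0.01, PV→PV p = 0.12, free
cross-connectivities), integrated with forward Euler (dt = 0.02 ms) or
Heun/RK2 (dt = 0.04 ms, noisy runs).  A mean-field N·p·g scaling rule lets
networks run downscaled with compensated conductances/probabilities.

The analysis defines the network frequency as the spectral peak of the
average membrane potential, detects population bursts with a
frequency-adaptive histogram and moving threshold (mean + 0.35 SD), labels
runs nonfiring / theta-stable / unstable / non-theta, and measures peak
EPSC/IPSC magnitudes onto recorded cells.  The E/I ratio **onto PV+
cells** separates two theta-generation regimes: Scenario B (ratio ≈ or
> 1 — the regime compatible with experiment, where postinhibitory rebound
plays a lesser role) versus Scenario A (ratio ≪ 1).

See `docs/methods.md` for the full procedure and design choices.

## Worked example

A deterministic strongly adapting PYR-only network at a ×0.1 desk scale
(1000 cells, conductance-compensated), then the full analysis chain:

```python
from thetanet import (pyr_network, rescale_network, DeterministicDriveSpec,
                      SimulationConfig, run, analyze_run)

net = rescale_network(pyr_network(g_pyr=0.064), 0.1, compensate="auto")
res = run(net, DeterministicDriveSpec(I_app=65.0),
          SimulationConfig(duration=10_000.0, seed=1))
rec = analyze_run(res)
print(round(rec["f_peak"], 2), rec["category"],
      round(rec["active_PYR_per_burst"] / rec["n_PYR"], 3))
```

prints

```
6.63 theta_stable 1.0
```

i.e. a stable ~6.6 Hz theta-band population rhythm in which essentially
every pyramidal cell fires on every burst — the signature result for
excitatory-only networks: theta is possible, but never sparse.  Adding the
PV+ population (`pyr_pv_network`) is what produces sparse PYR firing; the
E/I regime is then classified from the recorded currents:

```python
from thetanet import pyr_pv_network, OUDriveSpec, summarize_currents, classify_scenario

net = rescale_network(pyr_pv_network(g_pyr=0.014, c_pyr_pv=0.02, c_pv_pyr=0.3),
                      0.1, compensate="auto")
res = run(net, OUDriveSpec(g_e_mean=0.0, sigma_e=0.6),
          SimulationConfig(duration=4000.0, dt=0.04, integrator="rk2", seed=1))
summary = summarize_currents(res, rng=1)
print(round(summary.pv.epsc_mean), round(summary.pv.ipsc_mean),
      classify_scenario(summary).label)
```

prints

```
315 327 B
```

— large (~320 pA) excitatory peaks onto PV+ cells with an E/I ratio near
one: Scenario B.

A command-line layer wraps the same functionality:

```bash
thetanet simulate --config run.yaml --seed 1 --out out/
thetanet analyze --raster out/raster.tsv
thetanet currents --run out/ --seed 1
thetanet sweep --spec sweep.yaml --out sweep_out/
thetanet fixtures --kind sinusoidal --out fx/ --seed 0
```

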