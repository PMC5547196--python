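# Methods

## The model

`thetanet` simulates the intrinsic theta rhythm (3–12 Hz) of a CA1-like
hippocampal microcircuit as population bursting in networks of excitatory
pyramidal (PYR) cells and fast-firing parvalbumin-positive (PV+)
interneurons, with no oscillatory external input.

### Cells

Each cell is a two-variable quadratic integrate-and-fire model with a
recovery current (Izhikevich family):

    C_m dV/dt = k (V − v_r)(V − v_t) − u + I_shift + I_other − I_syn
       du/dt = a [ b (V − v_r) − u ]
    if V ≥ v_peak:  V ← c,  u ← u + d

with `k = k_low` for `V ≤ v_t` and `k_high` above (the two branches agree
at `v_t`, so the right-hand side is continuous).  Three built-in parameter
sets — weakly adapting PYR, strongly adapting PYR, and PV+ — are taken from
fits to whole-hippocampus preparation recordings (`cells.builtin_parameters`).
The positive subthreshold coupling `b = 3 nS` of the PYR sets produces
postinhibitory rebound, which is central to the excitatory–inhibitory theta
mechanism.

A caveat a user should know: the weakly adapting set's lateral f–I shift
(`I_shift = −45 pA`) gives it a step rheobase of roughly 48 pA in this
formulation (confirmed analytically from the nullclines and by simulation),
so "weak drive" regimes that make the strongly adapting set fire leave the
weakly adapting set silent.  The strongly adapting set's rheobase is a few
pA.

### Synapses

Connections are conductance-based with first-order kinetics: a presynaptic
spike releases a 1 mM, 1 ms square transmitter pulse; the open-channel
fraction obeys `ds/dt = α[T](1−s) − βs` and the current is
`I_syn = g·s·(V − E_rev)` with `E_rev = −15 mV` (AMPA) or `−85 mV`
(GABA_A).  The rates come from the reported rise/decay time constants via
`β = 1/τ_D`, `α = 1/τ_R − 1/τ_D`, chosen so the during-pulse relaxation
time equals `τ_R` and the post-pulse decay equals `τ_D` simultaneously.
Gating is advanced by the exact exponential solutions of the two branches
(the pulse is piecewise-constant), which is unconditionally stable and
keeps `s ∈ [0, 1]` for any step.  Gating is kept per presynaptic source
per connection class rather than per synapse — mathematically identical for
class-uniform parameters (property-tested) and O(cells) instead of
O(edges) in state.  Overlapping transmitter pulses merge (the pulse height
is a concentration, it does not sum).  Fractional pulse-boundary overlap
within a step is ignored (dt ≤ 0.04 ms against a 1 ms pulse).

### Drive

Deterministic runs give each PYR cell a constant current drawn once from
N(I_app, σ_app²).  Noisy runs instead use a fluctuating excitatory
conductance per cell following an Ornstein–Uhlenbeck process with
τ_e = 2.73 ms, advanced once per global step by its exact Gaussian
transition (no Euler–Maruyama step-size bias), independent across cells,
not clamped at zero, initialized at its mean.  In
excitatory–inhibitory networks the PV+ population receives no external
drive; its excitation comes entirely through the PYR→PV projection.

### Networks

The reference circuit has 10,000 PYR and 500 PV+ cells with directed
Erdős–Rényi connectivity: fixed recurrent probabilities (PYR→PYR 0.01,
PV→PV 0.12, no self-edges) and free cross-projection probabilities
c_PYR,PV and c_PV,PYR ∈ [0.01, 1].  Edge sets are sampled once per run
(quenched).  Default conductances: g_pv = 3 nS, g_pv-pyr = 8.7 nS,
g_pyr-pv = 1 nS (deterministic runs) or 3 nS (noisy runs); g_pyr is the
main swept parameter (0.014–0.094 nS).

### Integration

Clock-driven: forward Euler with dt = 0.02 ms for deterministic runs,
explicit second-order Runge–Kutta (Heun) with dt = 0.04 ms for noisy runs.
Within a step: OU advance → per-target conductance sums → membrane update
(Heun re-evaluates synaptic and drive currents at the stage voltage with
gating and OU conductance frozen at step start) → gating update (driven by
transmitter pulses from previous steps) → resets and spike recording.
Spike times are the end time of the step in which `V ≥ v_peak` was
detected, without interpolation.  Initial conditions: V ~ Uniform(−65,
−55) mV, u = 0, s = 0.  The inner loop is a numba-compiled kernel; runs
abort with a diagnostic if any |V| exceeds 10³ mV.  On a linearized cell
the Euler and Heun trajectories match a high-accuracy reference solution to
~1e−4 and ~1e−6 relative error respectively, and on a deterministic theta
network the two integrators' spectral peaks agree to well under 0.5 Hz.

## Downscaling (N·p·g rule)

Mean-field scaling makes the dynamics approximately invariant when the
product N_pre·p·g is preserved per projection.  `rescale_network` offers
three compensation modes:

- `g`: inflate per-connection conductance (keeps sparseness p);
- `p`: inflate connection probability (errors past p = 1);
- `auto` (default in sweeps/acceptance): inflate p up to 1, remainder
  into g.

`auto` preserves the mean *and* variance of per-cell synaptic input and the
per-event conductance quantum, which matters for PSC **peak** statistics:
under pure g-compensation a ×0.1 downscale makes single-connection events
10× larger, and measured peak EPSCs are then dominated by isolated events.
Conversely, when a cross-projection probability saturates at 1, `auto`
degenerates to all-to-all input and erases across-cell input heterogeneity;
for high-connectivity configurations (e.g. c_PYR,PV = 0.4, c_PV,PYR = 0.5)
`g` compensation preserves the heterogeneity that keeps PV+ participation
probabilistic, and is used for those points (their current magnitudes are
not the quantity of interest there).  Cross-scale consistency (×0.1 vs
×0.25, three seeds) of the theta peak is tested to ±20%.

Desk-scale defaults: sweeps run at ×0.25; the acceptance script runs most
configurations at ×0.1 (1000 PYR / 50 PV) with full-length durations (10 s
excitatory-only, 4 s excitatory–inhibitory) and three seeds per
configuration.  Two configurations need a gentler reduction, chosen for
identified fidelity reasons: the strongly noisy excitatory-only point
(g_e,mean = 1, σ_e = 0.6 nS) runs at ×0.25 because the population-activity
noise floor at ×0.1 makes the spectral argmax seed-fragile (slow network
rate fluctuations rival the theta peak), and the sparse
excitatory–inhibitory point (c = (0.02, 0.3)) runs at ×0.2 so that the
PV→PV projection stays below probability saturation and the PV population
(100 cells) is large enough for graded participation — at ×0.1 the
inflated PV participation biases IPSC peaks onto PV+ cells upward by
~60%.  A full reproduction stays near ten minutes on one core; full scale
is a flag away (`scale=1`) but takes ~10 min per run.

## Analysis chain

1. **Network frequency.**  The population activity is the average membrane
   potential of all cells (post-reset values, recorded every step).
   `f_peak` is the argmax of the post-transient (first 500 ms dropped),
   mean-removed, unwindowed periodogram, searched over (0.5, 100] Hz.  The
   periodogram is smoothed with a 0.5 Hz boxcar first: raw periodogram
   ordinates have unit relative variance, and in downscaled networks (noise
   floor ~√10 higher than reference scale) the raw argmax intermittently
   lands on isolated noise bins.  The smoothing width is far below the
   theta peak spacing and leaves sharp deterministic peaks in place.
2. **Burst binning.**  PYR spikes are binned at the frequency-adaptive
   width `int(p1·round((p2·e^(−p3·f_peak + p4) + p5)/p1))` ms with
   p1=2, p2=2.0264, p3=0.2656, p4=2.9288, p5=5.7907 (≈22 ms at 3 Hz to
   8 ms at 12 Hz; the published bracketing of this formula is ambiguous and
   this reading reproduces the stated ≈23–7 ms range within ±1 ms), then
   normalized to the post-transient maximum.
3. **Burst detection.**  Threshold = local mean + 0.35·SD over a centered
   window of ≈5/f_peak s (clipped at the trace ends; population SD).  A
   burst boundary lies midway between each upward crossing and the previous
   downward crossing; boundaries closer than 1000/(2.5·f_peak) ms are
   merged (keep-first).  Candidate bursts with normalized peak−trough
   < 0.2 are discarded.  Burst amplitude is the normalized peak count in
   the interval.
4. **Metrics.**  Per burst (boundary-to-boundary): width, distinct active
   cells, total spikes; sweep rows carry per-population averages and
   spikes-per-cell-per-100-bursts.
5. **Categorization.**  Nonfiring if the network emits fewer than 300
   spikes per burst cycle (post-transient rate / f_peak; the threshold
   scales with n_PYR/10,000 for downscaled nets — per burst *cycle*, not
   per histogram bin, since the per-bin reading would misclassify sparse
   E-I theta networks whose reference categorization is theta).  Otherwise
   theta runs (f_peak ∈ [3, 12] Hz) are "unstable" when there are at least
   two occurrences of two consecutive burst amplitudes each collapsing by
   more than 79% (the source description of this rule is worded as a
   stability criterion, which contradicts its usage; it is implemented as
   an instability detector), else "theta_stable"; out-of-band rhythms are
   "non_theta".
6. **Currents.**  EPSC/IPSC traces are recorded for 100 PYR and 50 PV+
   cells (seeded choice; sampled every 0.2 ms — PSC decay constants are
   2–3.5 ms, so peaks are resolved).  Peak magnitudes: prominent local
   maxima of |trace| after the first 1 s, with minimum prominence one
   quarter of the trace range (emulating the default selectivity of
   interactive peak finders; without it every sub-wiggle of a barrage
   counts), discarding peaks below a tenth of the maximum.  Averages are
   taken per cell, then across a seeded choice of 5 PYR and 3 PV+ cells.
   Display values are rounded to table granularity (PYR EPSC to 1 pA,
   others to 5 pA); classification always uses unrounded values.
7. **Scenario.**  The excitatory/inhibitory ratio onto PV+ cells alone
   classifies the regime: Scenario B ("close to or above 1", implemented
   as ≥ 0.8, exposed in config) versus Scenario A.  A consistency checker
   compares a summary against whole-hippocampus constraints (PYR EPSC
   < 20 pA, IPSC ≈ 200 pA within a factor of 3, PV EPSC ≤ 1000 pA, PV
   IPSC ≈ 200 pA, PYR ratio < 1, PV ratio > 1).

## Synthetic fixtures

`fixtures` generates ground-truth inputs that emulate what the analysis
assumes, not the biophysics: sinusoidally rate-modulated Poisson rasters
(known burst frequency; thinning algorithm), homogeneous Poisson rasters
(negative control), packet rasters (exact per-burst participation counts,
jittered packet times), PSC traces as exponential-decay event trains with
known amplitudes (events kept ≥ 5 decay constants apart so the true peak
list is unambiguous), and downscaled network specs.  Burst-detector tests
use population spike counts comparable to the reference scale (hundreds per
bin); with much smaller counts the normalized histogram's Poisson noise
exceeds the 0.2 peak−trough rejection rule, which is a property of the
procedure, not of the detector implementation.  Passing fixture tests
demonstrate correct detection on rasters with the assumed statistical
structure; they do not establish robustness to non-Poisson spike trains,
rate drift, or measurement artifacts of experimental data.

## Numerical and design choices

- Seeding: one master seed spawns independent connectivity / initial-
  condition / noise streams (`numpy` SeedSequence); runs are bit-for-bit
  reproducible.
- The recovery variable is unbounded, per the model definition.
- Burst boundaries need at least one preceding downward crossing; leading
  partial cycles are not counted as bursts.
- `analyze_run` reports burst metrics whenever bursts are detectable, with
  the category label alongside, so summary quantities do not hinge on the
  nonfiring threshold.
- Degenerate inputs: empty rasters give empty histograms and the
  "nonfiring" label; constant traces have no spectral peak (None); empty
  grids give empty sweep tables; zero-connectivity networks give empty
  current summaries and an "indeterminate" scenario.

## Known limitations

- Quantities tied to the motivating deterministic excitatory–inhibitory
  example (PYR network at I_app = 30 pA, g_pyr = 0.024 nS coupled to PV+
  with c = (0.01, 0.2)) reproduce qualitatively (stable theta, frequency
  rise on coupling) but land at ~7.7 Hz with ~49% PYR participation in
  this implementation, versus the reported ≈6.7 Hz with <20%; the
  uncoupled baseline (3.1–3.2 Hz) and all table-grade
  excitatory–inhibitory results reproduce closely.
- At aggressive downscaling (×0.1) IPSC magnitudes onto PV+ cells run
  ~50% above reference values and the Scenario-B E/I ratio onto PV+
  hovers near 1 rather than ~1.7; at the ×0.2 scale used for that
  configuration the ratio is ~1.2 and the classification is stable, but
  IPSC values still run ~30% high.
- No conduction delays, short-term plasticity, NMDA/GABA_B kinetics,
  spatial structure, or LFP modelling; O-LM and other interneuron classes
  are out of scope.
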