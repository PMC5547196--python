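"""Kinetic synapse model: rate mapping, gating updates, pulses, currents."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thetanet.synapses import (
    E_EXC,
    E_INH,
    GatingState,
    SYNAPSE_CLASSES,
    builtin_synapse_class,
    rates_from_time_constants,
    synaptic_current,
    trigger_pulse,
    update_gating,
)


@pytest.mark.parametrize("tau_R,tau_D,alpha,beta", [
    (0.27, 1.7, 3.1155, 0.5882),   # fast inhibitory kinetics
    (0.5, 3.0, 1.6667, 0.3333),    # recurrent excitatory kinetics
])
def test_rate_mapping(tau_R, tau_D, alpha, beta):
    a, b = rates_from_time_constants(tau_R, tau_D)
    assert a == pytest.approx(alpha, abs=1e-4)
    assert b == pytest.approx(beta, abs=1e-4)
    # the mapping must reproduce both time constants simultaneously
    assert 1.0 / (a + b) == pytest.approx(tau_R)
    assert 1.0 / b == pytest.approx(tau_D)


@pytest.mark.parametrize("tau_R,tau_D", [(1.0, 1.0), (3.0, 1.0), (0.0, 1.0)])
def test_degenerate_time_constants_rejected(tau_R, tau_D):
    with pytest.raises(ValueError):
        rates_from_time_constants(tau_R, tau_D)


def test_builtin_classes():
    assert set(SYNAPSE_CLASSES) == {"PV->PV", "PV->PYR", "PYR->PV", "PYR->PYR"}
    for label, syn in SYNAPSE_CLASSES.items():
        assert 0 < syn.tau_R < syn.tau_D
        assert 0 < syn.s_inf < 1
        expected_erev = E_EXC if label.startswith("PYR") else E_INH
        assert syn.E_rev == expected_erev


def test_gating_decay_halves_at_log_two_decay_times():
    syn = builtin_synapse_class("PYR->PYR")
    state = update_gating(GatingState(s=0.8), syn.tau_D * math.log(2), syn,
                          transmitter_on=False)
    assert state.s == pytest.approx(0.4)


def test_gating_zero_is_absorbing_without_transmitter():
    syn = builtin_synapse_class("PV->PV")
    state = update_gating(GatingState(s=0.0), 5.0, syn, transmitter_on=False)
    assert state.s == 0.0


def test_sustained_transmitter_saturates_at_s_inf():
    syn = builtin_synapse_class("PYR->PV")
    state = GatingState(s=0.0)
    state = update_gating(state, 50.0 * syn.tau_s, syn, transmitter_on=True)
    assert state.s == pytest.approx(syn.s_inf, rel=1e-6)


@settings(deadline=None, derandomize=True)
@given(s0=st.floats(0.0, 1.0), dt=st.floats(1e-3, 50.0),
       on=st.booleans())
def test_gating_stays_in_unit_interval(s0, dt, on):
    syn = builtin_synapse_class("PV->PYR")
    state = update_gating(GatingState(s=s0), dt, syn, transmitter_on=on)
    assert 0.0 <= state.s <= 1.0


def test_pulse_merging():
    syn = builtin_synapse_class("PYR->PYR")
    state = trigger_pulse(GatingState(), 10.0, syn)
    assert state.pulse_end_time == 11.0
    assert state.transmitter_on(10.5) and not state.transmitter_on(11.0)
    state = trigger_pulse(state, 10.5, syn)
    assert state.pulse_end_time == 11.5   # overlapping pulses merge
    state = trigger_pulse(state, 9.0, syn)
    assert state.pulse_end_time == 11.5   # earlier spike cannot shorten it


def test_no_spike_means_no_transmitter():
    state = GatingState()
    assert not state.transmitter_on(0.0)
    assert state.s == 0.0


@pytest.mark.parametrize("g,s,V,E,expected", [
    (8.7, 1.0, -65.0, -85.0, 174.0),   # inhibitory driving force
    (5.0, 0.7, -15.0, -15.0, 0.0),     # at reversal
    (5.0, 0.0, -60.0, -15.0, 0.0),     # closed channels
])
def test_synaptic_current(g, s, V, E, expected):
    assert synaptic_current(g, s, V, E) == pytest.approx(expected)


def test_impulse_response_peaks_at_pulse_end_and_decays_with_tau_d():
    """A single 1 ms pulse from rest: peak near pulse end, decay tau within 1%."""
    syn = builtin_synapse_class("PYR->PYR")
    dt = 0.01
    state = GatingState(s=0.0)
    t, trace = 0.0, []
    while t < 20.0:
        state = update_gating(state, dt, syn, transmitter_on=(t < 1.0))
        t += dt
        trace.append(state.s)
    trace = np.asarray(trace)
    assert abs(np.argmax(trace) * dt - 1.0) <= 2 * dt
    # log-linear fit of the tail
    tail = trace[int(2.0 / dt): int(14.0 / dt)]
    tt = np.arange(tail.size) * dt
    slope = np.polyfit(tt, np.log(tail), 1)[0]
    assert -1.0 / slope == pytest.approx(syn.tau_D, rel=0.01)


def test_per_source_gating_equals_per_synapse_gating():
    """Summed per-source gating reproduces per-synapse bookkeeping exactly.

    On a toy 5x5 network with class-uniform kinetics, a gating variable per
    presynaptic source gives the same postsynaptic conductance as one per
    synapse, step by step.
    """
    rng = np.random.default_rng(7)
    syn = builtin_synapse_class("PYR->PV")
    n_pre, n_post, dt, n_steps = 5, 5, 0.05, 400
    adj = rng.random((n_pre, n_post)) < 0.6
    spike_steps = {j: set(rng.integers(0, n_steps, size=6).tolist())
                   for j in range(n_pre)}

    per_source = [GatingState() for _ in range(n_pre)]
    per_synapse = {(j, i): GatingState()
                   for j in range(n_pre) for i in range(n_post) if adj[j, i]}
    for step in range(n_steps):
        t = step * dt
        s_total_src = np.zeros(n_post)
        for j in range(n_pre):
            for i in range(n_post):
                if adj[j, i]:
                    s_total_src[i] += per_source[j].s
        s_total_syn = np.zeros(n_post)
        for (j, i), g in per_synapse.items():
            s_total_syn[i] += g.s
        np.testing.assert_allclose(s_total_src, s_total_syn, atol=1e-14)

        for j in range(n_pre):
            on = per_source[j].transmitter_on(t)
            per_source[j] = update_gating(per_source[j], dt, syn, on)
        for (j, i), g in list(per_synapse.items()):
            per_synapse[(j, i)] = update_gating(g, dt, syn, g.transmitter_on(t))
        for j in range(n_pre):
            if step in spike_steps[j]:
                per_source[j] = trigger_pulse(per_source[j], t + dt, syn)
                for i in range(n_post):
                    if adj[j, i]:
                        per_synapse[(j, i)] = trigger_pulse(
                            per_synapse[(j, i)], t + dt, syn)
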