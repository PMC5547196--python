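"""First-order kinetic conductance synapses.

A presynaptic spike releases a square transmitter pulse [T] of height 1 mM
lasting 1 ms.  The fraction of open channels ``s`` obeys

    ds/dt = alpha [T] (1 - s) - beta s

so that while transmitter is present s relaxes toward
``s_inf = alpha/(alpha+beta)`` with time constant ``tau_s = 1/(alpha+beta)``,
and after the pulse it decays as ``exp(-beta t)``.  The postsynaptic current
is ``I_syn = g * s * (V - E_rev)`` (pA, with g in nS and V in mV), which is
subtracted in the cell equation.

The forward/backward rates are derived from the experimentally reported rise
and decay time constants via ``beta = 1/tau_D`` and
``alpha = 1/tau_R - 1/tau_D``, so the during-pulse time constant equals
``tau_R`` and the post-pulse decay equals ``tau_D``.

Built-in connection classes (rise/decay ms, reversal mV, excitatory -15 /
inhibitory -85):

    PV->PV    0.27 / 1.7   inhibitory
    PV->PYR   0.3  / 3.5   inhibitory
    PYR->PV   0.37 / 2.1   excitatory
    PYR->PYR  0.5  / 3     excitatory

Updates use the exact exponential solutions of the two branches (the
transmitter concentration is piecewise constant), which keeps s in [0, 1]
unconditionally.  Rapidly repeated presynaptic spikes merge their transmitter
pulses: [T] saturates at the pulse height and never sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "SynapseClassParameters",
    "GatingState",
    "SYNAPSE_CLASSES",
    "E_EXC",
    "E_INH",
    "builtin_synapse_class",
    "rates_from_time_constants",
    "update_gating",
    "trigger_pulse",
    "synaptic_current",
]

E_EXC = -15.0  # excitatory reversal potential (mV)
E_INH = -85.0  # inhibitory reversal potential (mV)

PULSE_HEIGHT_MM = 1.0   # transmitter pulse height (mM)
PULSE_DURATION_MS = 1.0  # transmitter pulse duration (ms)


def rates_from_time_constants(tau_R: float, tau_D: float) -> tuple[float, float]:
    """Map (rise, decay) time constants (ms) to kinetic rates (alpha, beta).

    beta = 1/tau_D (1/ms); alpha = 1/tau_R - 1/tau_D (1/(mM*ms), with the
    1 mM pulse height folded in).  Requires 0 < tau_R < tau_D, otherwise
    alpha would be non-positive.
    """
    if not (0 < tau_R < tau_D):
        raise ValueError(f"require 0 < tau_R < tau_D, got tau_R={tau_R}, tau_D={tau_D}")
    beta = 1.0 / tau_D
    alpha = 1.0 / tau_R - beta
    return alpha, beta


@dataclass(frozen=True)
class SynapseClassParameters:
    """Kinetic and conductance parameters of one connection class."""

    label: str
    tau_R: float          # rise time constant (ms)
    tau_D: float          # decay time constant (ms)
    E_rev: float          # reversal potential (mV)
    g: float = 0.0        # maximal conductance per connection (nS)
    pulse_height: float = PULSE_HEIGHT_MM
    pulse_duration: float = PULSE_DURATION_MS

    @property
    def alpha(self) -> float:
        return rates_from_time_constants(self.tau_R, self.tau_D)[0]

    @property
    def beta(self) -> float:
        return rates_from_time_constants(self.tau_R, self.tau_D)[1]

    @property
    def s_inf(self) -> float:
        """Saturation of s under sustained transmitter, alpha/(alpha+beta)."""
        a, b = self.alpha, self.beta
        return a / (a + b)

    @property
    def tau_s(self) -> float:
        """During-pulse relaxation time constant 1/(alpha+beta); equals tau_R."""
        return 1.0 / (self.alpha + self.beta)

    def with_conductance(self, g: float) -> "SynapseClassParameters":
        if g < 0:
            raise ValueError("conductance must be non-negative")
        return replace(self, g=g)


SYNAPSE_CLASSES = {
    "PV->PV": SynapseClassParameters("PV->PV", tau_R=0.27, tau_D=1.7, E_rev=E_INH),
    "PV->PYR": SynapseClassParameters("PV->PYR", tau_R=0.3, tau_D=3.5, E_rev=E_INH),
    "PYR->PV": SynapseClassParameters("PYR->PV", tau_R=0.37, tau_D=2.1, E_rev=E_EXC),
    "PYR->PYR": SynapseClassParameters("PYR->PYR", tau_R=0.5, tau_D=3.0, E_rev=E_EXC),
}


def builtin_synapse_class(label: str) -> SynapseClassParameters:
    try:
        return SYNAPSE_CLASSES[label]
    except KeyError:
        raise KeyError(
            f"unknown synapse class {label!r}; valid: {', '.join(SYNAPSE_CLASSES)}"
        ) from None


@dataclass
class GatingState:
    """Gating of one presynaptic source within one connection class.

    ``pulse_end_time`` is the time (ms) until which transmitter is present;
    overlapping pulses merge into a single on-interval.
    """

    s: float = 0.0
    pulse_end_time: float = -math.inf

    def transmitter_on(self, t: float) -> bool:
        return t < self.pulse_end_time


def trigger_pulse(
    state: GatingState, spike_time: float, params: SynapseClassParameters
) -> GatingState:
    """Register a presynaptic spike: transmitter is on until spike_time + 1 ms.

    Overlapping pulses merge (the end time is the max of the candidates).
    """
    end = spike_time + params.pulse_duration
    return GatingState(s=state.s, pulse_end_time=max(state.pulse_end_time, end))


def update_gating(
    state: GatingState,
    dt: float,
    params: SynapseClassParameters,
    transmitter_on: bool,
) -> GatingState:
    """Advance s over an interval dt with constant transmitter state.

    Uses the exact exponential solution of the kinetic equation for either
    branch, so s stays in [0, 1] for any dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if transmitter_on:
        s_inf = params.s_inf
        s = s_inf + (state.s - s_inf) * math.exp(-dt / params.tau_s)
    else:
        s = state.s * math.exp(-params.beta * dt)
    return GatingState(s=s, pulse_end_time=state.pulse_end_time)


def synaptic_current(g: float, s_total: float, V: float, E_rev: float) -> float:
    """Postsynaptic current g * s_total * (V - E_rev) in pA.

    ``s_total`` is the summed gating over connected presynaptic sources; the
    returned value is subtracted in the membrane equation, so a positive
    value at V > E_rev is hyperpolarizing.
    """
    return g * s_total * (V - E_rev)
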