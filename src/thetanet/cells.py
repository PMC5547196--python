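"""Single-cell models for CA1 pyramidal (PYR) and parvalbumin-positive (PV+) cells.

The cell model is a two-variable integrate-and-fire hybrid of the Izhikevich
family: a fast membrane-potential variable ``V`` (mV) driven by a quadratic
current-voltage relation, and a slow recovery current ``u`` (pA) that produces
spike-frequency adaptation (PYR) or fast-firing dynamics (PV+).  The quadratic
scaling factor ``k`` switches between a subthreshold value ``k_low`` (for
``V <= v_t``) and a suprathreshold value ``k_high``, which lets the model
reproduce both the subthreshold current-voltage relation and the spike width.

Dynamics::

    C_m dV/dt = k (V - v_r)(V - v_t) - u + I_shift + I_other - I_syn
    du/dt     = a [ b (V - v_r) - u ]
    if V >= v_peak:  V <- c,  u <- u + d   (spike)

Three built-in parameter sets are provided: weakly adapting PYR, strongly
adapting PYR, and fast-firing PV+.  They were fit to whole-cell recordings
from the intact (whole) hippocampus preparation; the strongly adapting PYR
set has a rheobase near 0 pA, the weakly adapting set near 5 pA (implemented
via the lateral f-I shift current ``I_shift``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np

__all__ = [
    "CellParameters",
    "CellState",
    "CELL_LABELS",
    "builtin_parameters",
    "derivatives",
    "apply_reset",
    "f_i_curve",
    "single_cell_spike_times",
]

CELL_LABELS = ("weakly_adapting_PYR", "strongly_adapting_PYR", "PV")


@dataclass(frozen=True)
class CellParameters:
    """Parameter set of one cell class.

    Units: voltages mV, currents pA, conductances nS, capacitance pF,
    rate constant ``a`` in 1/ms, ``k`` in nS/mV.
    """

    label: str
    v_r: float      # resting potential (mV)
    v_t: float      # instantaneous threshold (mV)
    v_peak: float   # spike cutoff (mV)
    a: float        # recovery time constant (1/ms)
    b: float        # subthreshold V-u coupling (nS)
    c: float        # post-spike reset potential (mV)
    d: float        # after-spike recovery increment (pA)
    k_low: float    # subthreshold quadratic scaling (nS/mV)
    k_high: float   # suprathreshold quadratic scaling (nS/mV)
    C_m: float      # membrane capacitance (pF)
    I_shift: float  # lateral f-I shift current (pA)

    def __post_init__(self) -> None:
        if not (self.v_r < self.v_t < self.v_peak):
            raise ValueError(
                f"require v_r < v_t < v_peak, got {self.v_r}, {self.v_t}, {self.v_peak}"
            )
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        if self.k_low <= 0 or self.k_high < self.k_low:
            raise ValueError("require 0 < k_low <= k_high")

    def with_overrides(self, **kwargs) -> "CellParameters":
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class CellState:
    """Instantaneous state of one cell: membrane potential V (mV), recovery u (pA)."""

    V: float
    u: float


_BUILTIN = {
    "weakly_adapting_PYR": CellParameters(
        label="weakly_adapting_PYR",
        v_r=-61.8, v_t=-57.0, v_peak=22.6,
        a=0.00008, b=3.0, c=-65.8, d=5.0,
        k_low=0.5, k_high=3.3, C_m=300.0, I_shift=-45.0,
    ),
    "strongly_adapting_PYR": CellParameters(
        label="strongly_adapting_PYR",
        v_r=-61.8, v_t=-57.0, v_peak=22.6,
        a=0.0012, b=3.0, c=-65.8, d=10.0,
        k_low=0.1, k_high=3.3, C_m=115.0, I_shift=0.0,
    ),
    "PV": CellParameters(
        label="PV",
        v_r=-60.6, v_t=-43.1, v_peak=-2.5,
        a=0.1, b=-0.1, c=-67.0, d=0.1,
        k_low=1.7, k_high=14.0, C_m=90.0, I_shift=0.0,
    ),
}


def builtin_parameters(label: str) -> CellParameters:
    """Return the built-in parameter set for one of the three cell classes.

    Raises
    ------
    KeyError
        If ``label`` is not one of ``CELL_LABELS``.
    """
    try:
        return _BUILTIN[label]
    except KeyError:
        raise KeyError(
            f"unknown cell label {label!r}; valid labels: {', '.join(CELL_LABELS)}"
        ) from None


def derivatives(
    state: CellState,
    p: CellParameters,
    I_syn: float = 0.0,
    I_other: float = 0.0,
) -> tuple[float, float]:
    """Right-hand side of the cell model: (dV/dt in mV/ms, du/dt in pA/ms).

    ``I_syn`` follows the convention that it is *subtracted* (a positive
    synaptic current g*s*(V - E_rev) hyperpolarizes); ``I_other`` is added.
    The quadratic scaling uses k_low when V <= v_t, k_high otherwise; both
    branches agree at V = v_t where the quadratic term vanishes.
    """
    V, u = state.V, state.u
    k = p.k_low if V <= p.v_t else p.k_high
    dV = (k * (V - p.v_r) * (V - p.v_t) - u + p.I_shift + I_other - I_syn) / p.C_m
    du = p.a * (p.b * (V - p.v_r) - u)
    return dV, du


def apply_reset(state: CellState, p: CellParameters) -> tuple[CellState, bool]:
    """Apply the spike/reset rule after an integration step.

    Returns the (possibly) updated state and a flag that is True iff a spike
    occurred (V had reached v_peak, so V was reset to c and u incremented by d).
    """
    if state.V >= p.v_peak:
        return CellState(V=p.c, u=state.u + p.d), True
    return state, False


def single_cell_spike_times(
    p: CellParameters,
    I_const: float,
    duration: float,
    dt: float = 0.02,
    V0: float | None = None,
    u0: float = 0.0,
) -> np.ndarray:
    """Forward-Euler simulation of one isolated cell under constant current.

    Returns spike times in ms.  Used for f-I characterization and as an
    internal oracle for the network simulator.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    from ._kernel import single_cell_euler

    V0 = p.v_r if V0 is None else V0
    return single_cell_euler(
        float(V0), float(u0), p.v_r, p.v_t, p.v_peak, p.a, p.b, p.c, p.d,
        p.k_low, p.k_high, p.C_m, p.I_shift, float(I_const), float(dt),
        int(round(duration / dt)),
    )


def f_i_curve(
    p: CellParameters,
    current_values,
    duration: float = 1000.0,
    dt: float = 0.02,
) -> np.ndarray:
    """Steady firing rate (Hz) versus injected current (pA) for one cell.

    Each current is applied from rest for ``duration`` ms (>= 1 s recommended)
    and the rate is the spike count divided by the duration.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rates = np.empty(len(current_values))
    for i, I in enumerate(current_values):
        spikes = single_cell_spike_times(p, float(I), duration, dt=dt)
        rates[i] = len(spikes) / (duration / 1000.0)
    return rates


def export_f_i_curve(path, current_values, rates) -> None:
    """Write an f-I curve as two-column delimited text (current_pA, rate_Hz)."""
    arr = np.column_stack([np.asarray(current_values, float), np.asarray(rates, float)])
    np.savetxt(path, arr, fmt="%.6g", delimiter="\t", header="current_pA\trate_Hz")
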