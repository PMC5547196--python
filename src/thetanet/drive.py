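"""External ("other") input drives.

Two kinds are used.  Deterministic networks give each cell a constant tonic
current drawn once per run from N(I_app, sigma_app^2) (pA).  Noisy networks
instead give each cell a fluctuating excitatory conductance g_e(t) following
a mean-reverting Ornstein-Uhlenbeck process

    dg_e/dt = -(g_e - g_e_mean)/tau_e + sqrt(2 sigma_e^2 / tau_e) * chi(t)

with tau_e = 2.73 ms and chi an independent unit-variance Gaussian white
noise per cell; the resulting current is I_other = -g_e(t) (V - E_exc).

The process is advanced by its exact Gaussian transition rather than
Euler-Maruyama, which removes step-size bias in the stationary variance.
g_e is not clamped at zero; transient negative excursions are allowed, as in
the point-conductance formulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synapses import E_EXC

__all__ = [
    "TAU_E_MS",
    "DeterministicDriveSpec",
    "OUDriveSpec",
    "sample_tonic_drive",
    "advance_ou",
    "ou_current",
]

TAU_E_MS = 2.73  # OU time constant for excitatory conductance noise (ms)


@dataclass(frozen=True)
class DeterministicDriveSpec:
    """Constant tonic currents: per-cell draw from N(I_app, sigma_app^2) pA."""

    I_app: float = 0.0
    sigma_app: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_app < 0:
            raise ValueError("sigma_app must be non-negative")


@dataclass(frozen=True)
class OUDriveSpec:
    """Fluctuating excitatory conductance drive (nS)."""

    g_e_mean: float = 0.0
    sigma_e: float = 0.0
    tau_e: float = TAU_E_MS
    E_rev: float = E_EXC

    def __post_init__(self) -> None:
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be non-negative")
        if self.tau_e <= 0:
            raise ValueError("tau_e must be positive")


def sample_tonic_drive(
    spec: DeterministicDriveSpec, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw one tonic current per cell (pA), fixed for the whole run.

    Values are not truncated: with large sigma_app some cells may receive
    negative (hyperpolarizing) drive.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if spec.sigma_app == 0:
        return np.full(n_cells, spec.I_app, dtype=float)
    return rng.normal(spec.I_app, spec.sigma_app, size=n_cells)


def advance_ou(
    g, dt: float, spec: OUDriveSpec, rng: np.random.Generator
):
    """Exact OU transition over dt (ms); works elementwise on arrays.

    g' = mu + (g - mu) e^{-dt/tau} + sigma sqrt(1 - e^{-2 dt/tau}) z,
    z ~ N(0,1) independent per element.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    decay = math.exp(-dt / spec.tau_e)
    g = np.asarray(g, dtype=float)
    out = spec.g_e_mean + (g - spec.g_e_mean) * decay
    if spec.sigma_e > 0:
        sd = spec.sigma_e * math.sqrt(1.0 - decay * decay)
        out = out + sd * rng.standard_normal(size=g.shape if g.shape else None)
    return out if g.shape else float(out)


def ou_current(g, V, E_rev: float = E_EXC):
    """Drive current I_other = -g (V - E_rev) in pA (added in the cell equation)."""
    return -np.asarray(g, float) * (np.asarray(V, float) - E_rev) if np.ndim(g) or np.ndim(V) else -g * (V - E_rev)
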