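"""Network construction: populations, random projections, and size scaling.

The reference circuit is a CA1-like network of 10,000 excitatory PYR cells
(strongly adapting by default) and 500 fast-firing PV+ cells.  Recurrent
connection probabilities are fixed (PYR->PYR 0.01, PV->PV 0.12); the
cross-projection probabilities c_PYR,PV and c_PV,PYR are free parameters
explored over [0.01, 1].  Connectivity is random (Erdos-Renyi style, directed,
no self-edges in recurrent projections), sampled once per run.

A mean-field scaling relationship makes the dynamics approximately invariant
under compensated changes of cell number N, connection probability p, and
per-connection conductance g, provided the product N_pre * p * g per
projection is preserved.  ``rescale_network`` uses this to build downscaled
networks for desk-scale runs; by default the compensation goes into g so the
sparseness statistics (p) are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cells import builtin_parameters
from .synapses import SynapseClassParameters, builtin_synapse_class

__all__ = [
    "write_edge_list",
    "PopulationSpec",
    "ProjectionSpec",
    "NetworkSpec",
    "build_connectivity",
    "rescale_network",
    "pyr_network",
    "pyr_pv_network",
    "DEFAULT_N_PYR",
    "DEFAULT_N_PV",
]

DEFAULT_N_PYR = 10_000
DEFAULT_N_PV = 500

P_PYR_PYR = 0.01  # fixed recurrent PYR->PYR connection probability
P_PV_PV = 0.12    # fixed recurrent PV->PV connection probability

G_PV_DEFAULT = 3.0       # PV->PV maximal conductance (nS)
G_PV_PYR_DEFAULT = 8.7   # PV->PYR maximal conductance (nS)
G_PYR_PV_DETERMINISTIC = 1.0  # PYR->PV conductance used in deterministic runs (nS)
G_PYR_PV_NOISY = 3.0          # PYR->PV conductance used in noisy runs (nS)


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    size: int
    cell_label: str

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("population size must be non-negative")
        builtin_parameters(self.cell_label)  # validates the label


@dataclass(frozen=True)
class ProjectionSpec:
    """A directed projection between two populations.

    ``p`` is the independent per-pair connection probability and ``g`` the
    per-connection maximal conductance (nS); the kinetics and reversal come
    from the named synapse class.
    """

    source: str
    target: str
    p: float
    g: float
    synapse_label: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"connection probability must be in [0,1], got {self.p}")
        if self.g < 0:
            raise ValueError("conductance must be non-negative")
        builtin_synapse_class(self.synapse_label)

    @property
    def recurrent(self) -> bool:
        return self.source == self.target

    def synapse(self) -> SynapseClassParameters:
        return builtin_synapse_class(self.synapse_label).with_conductance(self.g)


def build_connectivity(
    n_source: int, n_target: int, p: float, rng: np.random.Generator,
    recurrent: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a directed random adjacency as parallel (pre, post) index arrays.

    Each ordered pair is included independently with probability p; for
    recurrent projections self-pairs are excluded.  At most one edge per pair.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"connection probability must be in [0,1], got {p}")
    if n_source == 0 or n_target == 0 or p == 0.0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    mask = rng.random((n_source, n_target)) < p
    if recurrent:
        np.fill_diagonal(mask, False)
    pre, post = np.nonzero(mask)
    return pre.astype(np.int64), post.astype(np.int64)


@dataclass(frozen=True)
class NetworkSpec:
    """Populations plus projections; adjacency is sampled at build time."""

    populations: tuple[PopulationSpec, ...]
    projections: tuple[ProjectionSpec, ...]
    scale: float = 1.0  # bookkeeping: size factor relative to the reference circuit

    def population(self, name: str) -> PopulationSpec:
        for pop in self.populations:
            if pop.name == name:
                return pop
        raise KeyError(f"no population named {name!r}")

    def population_slices(self) -> dict[str, slice]:
        """Global cell-index ranges, populations concatenated in declared order."""
        out, start = {}, 0
        for pop in self.populations:
            out[pop.name] = slice(start, start + pop.size)
            start += pop.size
        return out

    @property
    def n_cells(self) -> int:
        return sum(p.size for p in self.populations)

    def sample_adjacency(self, rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
        """Sample every projection's edge set (quenched for the whole run)."""
        out = []
        for proj in self.projections:
            pre, post = build_connectivity(
                self.population(proj.source).size,
                self.population(proj.target).size,
                proj.p, rng, recurrent=proj.recurrent,
            )
            out.append((pre, post))
        return out


def pyr_network(
    g_pyr: float,
    n_pyr: int = DEFAULT_N_PYR,
    p_pyr: float = P_PYR_PYR,
    cell_label: str = "strongly_adapting_PYR",
) -> NetworkSpec:
    """Excitatory-only PYR cell network with recurrent AMPA coupling."""
    return NetworkSpec(
        populations=(PopulationSpec("PYR", n_pyr, cell_label),),
        projections=(ProjectionSpec("PYR", "PYR", p_pyr, g_pyr, "PYR->PYR"),),
    )


def pyr_pv_network(
    g_pyr: float,
    c_pyr_pv: float,
    c_pv_pyr: float,
    g_pyr_pv: float = G_PYR_PV_NOISY,
    g_pv_pyr: float = G_PV_PYR_DEFAULT,
    g_pv: float = G_PV_DEFAULT,
    n_pyr: int = DEFAULT_N_PYR,
    n_pv: int = DEFAULT_N_PV,
    cell_label: str = "strongly_adapting_PYR",
) -> NetworkSpec:
    """Excitatory-inhibitory network: PYR population driving and driven by PV+.

    The PV+ population receives its excitation exclusively through the
    PYR->PV projection (no separate external drive to PV+ cells).
    """
    return NetworkSpec(
        populations=(
            PopulationSpec("PYR", n_pyr, cell_label),
            PopulationSpec("PV", n_pv, "PV"),
        ),
        projections=(
            ProjectionSpec("PYR", "PYR", P_PYR_PYR, g_pyr, "PYR->PYR"),
            ProjectionSpec("PYR", "PV", c_pyr_pv, g_pyr_pv, "PYR->PV"),
            ProjectionSpec("PV", "PYR", c_pv_pyr, g_pv_pyr, "PV->PYR"),
            ProjectionSpec("PV", "PV", P_PV_PV, g_pv, "PV->PV"),
        ),
    )


def rescale_network(
    spec: NetworkSpec, size_factor: float, compensate: str = "g"
) -> NetworkSpec:
    """Downscale population sizes while preserving N_pre * p * g per projection.

    Parameters
    ----------
    size_factor : float in (0, 1]
        Multiplier applied (rounded) to every population size.
    compensate : {"g", "p", "auto"}
        Which projection parameter absorbs the compensation.  "g" inflates
        per-connection conductances (sparseness p unchanged); "p" inflates
        connection probabilities (errors if a probability would exceed 1,
        suggesting g-only compensation); "auto" inflates p up to 1 and puts
        any remainder into g.  "auto" preserves both the mean and the
        variance of per-cell synaptic input as well as the per-event
        conductance quantum, which keeps PSC *peak* statistics comparable
        across scales.
    """
    if not (0 < size_factor <= 1):
        raise ValueError("size_factor must be in (0, 1]")
    if compensate not in ("g", "p", "auto"):
        raise ValueError("compensate must be 'g', 'p', or 'auto'")
    new_sizes = {
        pop.name: max(1, int(round(pop.size * size_factor)))
        for pop in spec.populations
    }
    pops = tuple(replace(pop, size=new_sizes[pop.name]) for pop in spec.populations)
    projs = []
    for proj in spec.projections:
        n_old = spec.population(proj.source).size
        n_new = new_sizes[proj.source]
        ratio = n_old / n_new
        if compensate == "g":
            projs.append(replace(proj, g=proj.g * ratio))
        elif compensate == "p":
            p_new = proj.p * ratio
            if p_new > 1.0:
                raise ValueError(
                    f"rescaled p={p_new:.3f} exceeds 1 for {proj.source}->{proj.target}; "
                    "use compensate='g'"
                )
            projs.append(replace(proj, p=p_new))
        else:  # auto: p up to 1, remainder into g
            p_new = min(1.0, proj.p * ratio)
            g_new = proj.g * (proj.p * ratio / p_new)
            projs.append(replace(proj, p=p_new, g=g_new))
    return NetworkSpec(populations=pops, projections=tuple(projs),
                       scale=spec.scale * size_factor)


def write_edge_list(pre, post, path) -> None:
    """Write a projection's edges as two-column delimited text (0-based)."""
    import numpy as _np
    arr = _np.column_stack([_np.asarray(pre, _np.int64),
                            _np.asarray(post, _np.int64)])
    _np.savetxt(path, arr, fmt="%d", delimiter="\t",
                header="pre_index\tpost_index")
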