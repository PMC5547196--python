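"""Spike raster container shared by the simulator, fixtures, and analysis."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeRaster"]


@dataclass
class SpikeRaster:
    """An event list of spikes: times (ms) with their cell indices.

    ``populations`` maps population names to slices of the global 0-based
    cell index range (populations are concatenated in declared order).
    """

    times: np.ndarray
    cells: np.ndarray
    n_cells: int
    duration: float
    populations: dict[str, slice] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.times.shape != self.cells.shape:
            raise ValueError("times and cells must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.cells = self.cells[order]
        if not self.populations:
            self.populations = {"all": slice(0, self.n_cells)}

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def select(self, population: str) -> "SpikeRaster":
        """Sub-raster of one population, cell indices re-based to 0."""
        sl = self.populations[population]
        mask = (self.cells >= sl.start) & (self.cells < sl.stop)
        return SpikeRaster(
            times=self.times[mask],
            cells=self.cells[mask] - sl.start,
            n_cells=sl.stop - sl.start,
            duration=self.duration,
            populations={population: slice(0, sl.stop - sl.start)},
        )

    def population_of(self, cell: int) -> str:
        for name, sl in self.populations.items():
            if sl.start <= cell < sl.stop:
                return name
        raise IndexError(f"cell {cell} outside all populations")
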