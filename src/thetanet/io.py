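"""Delimited-text raster I/O and declarative run configuration.

Rasters are tab-separated text with a comment header (lines starting with
``#``) carrying population layout and duration, followed by the columns
``time_ms  cell_index  population``.  Times round-trip to 1e-6 ms.

Run configurations are YAML mappings with the sections ``network``,
``drive``, ``simulation``, ``analysis``, and ``cells``; omitted keys take
the built-in defaults (reference network sizes, built-in cell classes,
standard integration settings) and unknown keys are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .burst import AnalysisParameters
from .cells import builtin_parameters
from .drive import DeterministicDriveSpec, OUDriveSpec
from .network import NetworkSpec, pyr_network, pyr_pv_network, rescale_network
from .raster import SpikeRaster
from .simulator import SimulationConfig, DT_EULER, DT_RK2

__all__ = [
    "read_raster",
    "write_raster",
    "RunConfig",
    "load_config",
    "dump_config",
    "echo_config",
]

_RASTER_COLUMNS = ("time_ms", "cell_index", "population")


def write_raster(raster: SpikeRaster, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# thetanet raster v1\n")
        fh.write(f"# duration_ms {raster.duration:.6f}\n")
        for name, sl in raster.populations.items():
            fh.write(f"# population {name} {sl.start} {sl.stop}\n")
        fh.write("\t".join(_RASTER_COLUMNS) + "\n")
        pops = raster.populations
        names = np.empty(raster.n_cells, dtype=object)
        for name, sl in pops.items():
            names[sl] = name
        for t, c in zip(raster.times, raster.cells):
            fh.write(f"{t:.6f}\t{c}\t{names[c]}\n")


def read_raster(path) -> SpikeRaster:
    path = Path(path)
    duration = None
    populations: dict[str, slice] = {}
    times, cells = [], []
    header_seen = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["duration_ms"]:
                    duration = float(parts[1])
                elif parts[:1] == ["population"]:
                    populations[parts[1]] = slice(int(parts[2]), int(parts[3]))
                continue
            if not header_seen:
                cols = tuple(line.split("\t"))
                missing = [c for c in _RASTER_COLUMNS if c not in cols]
                if missing:
                    raise ValueError(
                        f"{path}:{lineno}: missing column(s) {', '.join(missing)}")
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: malformed line {line!r}")
            try:
                times.append(float(fields[0]))
                cells.append(int(fields[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line {line!r}") from exc
    if not header_seen:
        raise ValueError(f"{path}: no raster header found")
    times = np.asarray(times)
    cells = np.asarray(cells, np.int64)
    if times.size and np.any(np.diff(times) < 0):
        warnings.warn(f"{path}: spike times not monotone; sorting")
    n_cells = (max(sl.stop for sl in populations.values()) if populations
               else (int(cells.max()) + 1 if cells.size else 0))
    if duration is None:
        duration = float(times.max()) if times.size else 0.0
    return SpikeRaster(times, cells, n_cells, duration, populations)


# --- run configuration -----------------------------------------------------

_NETWORK_KEYS = {
    "kind", "g_pyr", "c_pyr_pv", "c_pv_pyr", "g_pyr_pv", "g_pv_pyr", "g_pv",
    "n_pyr", "n_pv", "cell_label", "scale",
}
_DRIVE_KEYS = {"kind", "I_app", "sigma_app", "g_e_mean", "sigma_e", "tau_e"}
_SIM_KEYS = {
    "dt", "duration", "integrator", "transient_spikes", "transient_currents",
    "seed", "n_record_pyr", "n_record_pv", "record_dt",
}
_ANALYSIS_KEYS = set(AnalysisParameters.__dataclass_fields__)
_CELL_KEYS = {"v_r", "v_t", "v_peak", "a", "b", "c", "d", "k_low", "k_high",
              "C_m", "I_shift"}
_TOP_KEYS = {"network", "drive", "simulation", "analysis", "cells", "version"}


def _check_keys(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) in {section}: {', '.join(sorted(unknown))}; "
            f"valid keys: {', '.join(sorted(allowed))}")


@dataclass
class RunConfig:
    """Declarative description of one run (network, drive, integration, analysis)."""

    network: dict = field(default_factory=lambda: {"kind": "pyr", "g_pyr": 0.014})
    drive: dict = field(default_factory=lambda: {"kind": "deterministic"})
    simulation: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    cells: dict = field(default_factory=dict)  # per-class parameter overrides
    version: str = __version__

    def build_network(self) -> NetworkSpec:
        cfg = dict(self.network)
        _check_keys("network", cfg, _NETWORK_KEYS)
        kind = cfg.pop("kind", "pyr")
        scale = cfg.pop("scale", 1.0)
        if kind == "pyr":
            cfg.pop("c_pyr_pv", None), cfg.pop("c_pv_pyr", None)
            spec = pyr_network(**cfg)
        elif kind == "pyr_pv":
            spec = pyr_pv_network(**cfg)
        else:
            raise ValueError(f"unknown network kind {kind!r}; valid: pyr, pyr_pv")
        return spec if scale == 1.0 else rescale_network(spec, scale)

    def build_drive(self):
        cfg = dict(self.drive)
        _check_keys("drive", cfg, _DRIVE_KEYS)
        kind = cfg.pop("kind", "deterministic")
        if kind == "deterministic":
            return DeterministicDriveSpec(**cfg)
        if kind == "ou":
            return OUDriveSpec(**cfg)
        raise ValueError(f"unknown drive kind {kind!r}; valid: deterministic, ou")

    def build_simulation_config(self) -> SimulationConfig:
        cfg = dict(self.simulation)
        _check_keys("simulation", cfg, _SIM_KEYS)
        if "integrator" not in cfg:
            noisy = self.drive.get("kind") == "ou"
            cfg["integrator"] = "rk2" if noisy else "euler"
            cfg.setdefault("dt", DT_RK2 if noisy else DT_EULER)
        if "duration" not in cfg:
            cfg["duration"] = 4000.0 if self.network.get("kind") == "pyr_pv" else 10_000.0
        return SimulationConfig(**cfg)

    def build_analysis_parameters(self) -> AnalysisParameters:
        _check_keys("analysis", self.analysis, _ANALYSIS_KEYS)
        return AnalysisParameters(**self.analysis)

    def build_cell_overrides(self):
        if not self.cells:
            return None
        out = {}
        for pop_name, overrides in self.cells.items():
            _check_keys(f"cells.{pop_name}", overrides, _CELL_KEYS)
            label = ("PV" if pop_name == "PV"
                     else self.network.get("cell_label", "strongly_adapting_PYR"))
            out[pop_name] = builtin_parameters(label).with_overrides(**overrides)
        return out


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    _check_keys("config", raw, _TOP_KEYS)
    cfg = RunConfig(**{k: v for k, v in raw.items() if k != "version"})
    # validate every section eagerly so errors surface at load time
    cfg.build_network()
    cfg.build_drive()
    cfg.build_simulation_config()
    cfg.build_analysis_parameters()
    cfg.build_cell_overrides()
    return cfg


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def echo_config(config: RunConfig, outdir) -> Path:
    """Write the resolved config into an output directory for reproducibility."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    target = outdir / "config.yaml"
    dump_config(config, target)
    return target
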