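"""Parameter-grid sweeps over network, drive, and connectivity parameters.

A sweep point is a mapping of parameter names (``g_pyr``, ``I_app``,
``sigma_app``, ``g_e_mean``, ``sigma_e``, ``c_pyr_pv``, ``c_pv_pyr``,
``g_pyr_pv``, ``g_pv_pyr``) to values.  Points with cross-connectivities
build excitatory-inhibitory networks; presence of ``g_e_mean``/``sigma_e``
selects the fluctuating-conductance drive (RK2, dt 0.04 ms), otherwise the
tonic-current drive (Euler, dt 0.02 ms).  Excitatory-only runs last 10 s,
excitatory-inhibitory runs 4 s.

Sweeps default to a 0.25 downscaled network with N*p*g compensation
("auto": probability-preferring; full scale is the explicit ``scale=1``).  Rows are written
append-only and a completed (point, seed) key is skipped on rerun, so an
interrupted sweep resumes; failed runs are recorded with a reason code and
never abort the sweep.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .burst import AnalysisParameters, analyze_run
from .currents import classify_scenario, summarize_currents
from .drive import DeterministicDriveSpec, OUDriveSpec
from .network import pyr_network, pyr_pv_network, rescale_network
from .simulator import DT_EULER, DT_RK2, SimulationConfig, run

__all__ = ["SweepSpec", "configure_run", "run_point", "run_sweep",
           "summarize_plane", "CONNECTIVITY_PRESET"]

# the connectivity grid used for cross-projection explorations:
# resolution 0.01 from 0.01 to 0.1, then 0.1 steps up to 1
CONNECTIVITY_PRESET = tuple(np.round(np.arange(0.01, 0.1, 0.01), 2)) + tuple(
    np.round(np.arange(0.1, 1.0001, 0.1), 1))

_NETWORK_PARAMS = {"g_pyr", "c_pyr_pv", "c_pv_pyr", "g_pyr_pv", "g_pv_pyr", "g_pv"}
_DET_PARAMS = {"I_app", "sigma_app"}
_OU_PARAMS = {"g_e_mean", "sigma_e"}


def configure_run(params: dict, scale: float = 1.0, seed: int = 0,
                  duration: float | None = None, compensate: str = "auto"):
    """Build (network, drive, simulation config) for one parameter point.

    ``compensate`` selects how downscaling preserves N*p*g per projection
    (see ``rescale_network``); "auto" keeps per-event conductance quanta
    faithful while high cross-connectivity points may prefer "g" to retain
    input heterogeneity once probabilities saturate at 1.
    """
    unknown = set(params) - _NETWORK_PARAMS - _DET_PARAMS - _OU_PARAMS
    if unknown:
        raise ValueError(f"unknown sweep parameter(s): {', '.join(sorted(unknown))}")
    is_ei = "c_pyr_pv" in params or "c_pv_pyr" in params
    if is_ei:
        net_kwargs = {k: params[k] for k in _NETWORK_PARAMS if k in params}
        network = pyr_pv_network(**net_kwargs)
    else:
        network = pyr_network(g_pyr=params.get("g_pyr", 0.014))
    if scale != 1.0:
        network = rescale_network(network, scale, compensate=compensate)

    noisy = bool(_OU_PARAMS & set(params))
    if noisy:
        drive = OUDriveSpec(g_e_mean=params.get("g_e_mean", 0.0),
                            sigma_e=params.get("sigma_e", 0.0))
    else:
        drive = DeterministicDriveSpec(I_app=params.get("I_app", 0.0),
                                       sigma_app=params.get("sigma_app", 0.0))
    if duration is None:
        duration = 4000.0 if is_ei else 10_000.0
    config = SimulationConfig(
        dt=DT_RK2 if noisy else DT_EULER,
        integrator="rk2" if noisy else "euler",
        duration=duration,
        seed=seed,
    )
    return network, drive, config


def run_point(params: dict, scale: float = 1.0, seed: int = 0,
              duration: float | None = None,
              analysis: AnalysisParameters = AnalysisParameters(),
              compensate: str = "auto") -> dict:
    """Simulate and analyze one parameter point; returns a flat results row."""
    network, drive, config = configure_run(params, scale, seed, duration, compensate)
    result = run(network, drive, config)
    row = dict(params)
    row.update(seed=seed, scale=scale, status="ok", reason="")
    row.update(analyze_run(result, analysis))
    if "PV" in result.record_columns:
        summary = summarize_currents(result, rng=seed)
        row.update(
            epsc_pyr=summary.pyr.epsc_mean, ipsc_pyr=summary.pyr.ipsc_mean,
            ei_ratio_pyr=summary.pyr.ei_ratio,
            epsc_pv=summary.pv.epsc_mean, ipsc_pv=summary.pv.ipsc_mean,
            ei_ratio_pv=summary.pv.ei_ratio,
            scenario=classify_scenario(summary).label,
        )
    return row


@dataclass
class SweepSpec:
    """Grids (name -> values), replicate seeds, scale, and output location."""

    grids: dict[str, list] = field(default_factory=dict)
    seeds: tuple[int, ...] = (0, 1, 2)
    scale: float = 0.25
    duration: float | None = None
    out: str | Path | None = None

    def points(self):
        if not self.grids:
            return
        names = sorted(self.grids)
        for combo in itertools.product(*(self.grids[n] for n in names)):
            yield dict(zip(names, combo))


def _row_key(params: dict, seed: int) -> str:
    return ";".join(f"{k}={params[k]:g}" for k in sorted(params)) + f";seed={seed}"


def run_sweep(spec: SweepSpec, log=None) -> pd.DataFrame:
    """Run every (grid point, seed), appending rows atomically; resumable.

    Per-run failures are recorded as rows with ``status='failed'`` and a
    reason, and the sweep continues.
    """
    out_path = Path(spec.out) / "sweep_results.tsv" if spec.out else None
    done: set[str] = set()
    rows: list[dict] = []
    if out_path is not None and out_path.exists():
        prior = pd.read_csv(out_path, sep="\t")
        rows = prior.to_dict("records")
        done = set(prior["key"])
    for params in spec.points():
        for seed in spec.seeds:
            key = _row_key(params, seed)
            if key in done:
                continue
            try:
                row = run_point(params, spec.scale, seed, spec.duration)
            except Exception as exc:  # recorded, not raised: sweeps are auditable
                row = dict(params)
                row.update(seed=seed, scale=spec.scale,
                           status="failed", reason=f"{type(exc).__name__}: {exc}")
            row["key"] = key
            rows.append(row)
            done.add(key)
            if out_path is not None:
                out_path.parent.mkdir(parents=True, exist_ok=True)
                pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)
            if log is not None:
                log(f"{key}: {row.get('category', row['status'])}")
    return pd.DataFrame(rows)


def summarize_plane(table: pd.DataFrame, x: str = "c_pyr_pv",
                    y: str = "c_pv_pyr", value: str = "f_peak") -> pd.DataFrame:
    """Median-over-seeds map of ``value`` on the (x, y) grid.

    Cells where no seed produced a theta-categorized run are masked (NaN);
    grid cells absent from the table stay absent rather than interpolated.
    """
    ok = table[table["status"] == "ok"].copy()
    if "category" in ok.columns:
        theta = ok["category"] == "theta_stable"
        ok.loc[~theta, value] = np.nan
    return ok.pivot_table(index=y, columns=x, values=value, aggfunc="median",
                          dropna=False)
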