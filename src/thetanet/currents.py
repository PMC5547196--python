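"""EPSC/IPSC peak analysis and Scenario A/B classification.

During theta bursts each recorded cell receives barrages of excitatory and
inhibitory synaptic current.  The analysis measures the peak magnitudes of
the recorded EPSC and IPSC traces (first second discarded; peaks smaller
than one tenth of the largest peak ignored), averages within each cell and
then across a seeded choice of 5 PYR and 3 PV+ cells, and reports the
per-class excitatory/inhibitory (E/I) ratio.

Two theta-generation regimes are distinguished solely by the E/I ratio onto
PV+ cells: Scenario B (ratio close to or above 1, the regime consistent with
whole-hippocampus recordings) versus Scenario A (ratio well below 1, where
postinhibitory rebound dominates).  The "close to 1" band is implemented as
ratio >= 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "PopulationCurrents",
    "CurrentSummary",
    "ScenarioLabel",
    "SCENARIO_B_RATIO",
    "detect_current_peaks",
    "summarize_currents",
    "classify_scenario",
    "check_experimental_consistency",
]

SCENARIO_B_RATIO = 0.8  # PV-cell E/I ratio at or above which the run is Scenario B

N_ANALYZED_PYR = 5
N_ANALYZED_PV = 3


@dataclass(frozen=True)
class PopulationCurrents:
    """Across-cell statistics of peak PSC magnitudes for one cell class (pA)."""

    epsc_mean: float
    epsc_sd: float
    ipsc_mean: float
    ipsc_sd: float

    @property
    def ei_ratio(self) -> float:
        if self.ipsc_mean > 0:
            return self.epsc_mean / self.ipsc_mean
        return float("nan")

    @property
    def band(self) -> str:
        """Qualitative E/I band: '<<1', '<1', '~1', or '>1'."""
        r = self.ei_ratio
        if np.isnan(r):
            return "undefined"
        if r < 0.1:
            return "<<1"
        if r < SCENARIO_B_RATIO:
            return "<1"
        if r <= 1.2:
            return "~1"
        return ">1"


@dataclass(frozen=True)
class CurrentSummary:
    pyr: PopulationCurrents
    pv: PopulationCurrents | None   # None for excitatory-only networks
    n_pyr_cells: int = N_ANALYZED_PYR
    n_pv_cells: int = N_ANALYZED_PV

    def rounded(self) -> dict:
        """Display values at table granularity (PYR EPSC to 1 pA, rest to 5 pA).

        Classification always uses the unrounded values.
        """
        def r5(x):
            return 5 * round(x / 5)
        out = {
            "EPSC_PYR_pA": round(self.pyr.epsc_mean),
            "IPSC_PYR_pA": r5(self.pyr.ipsc_mean),
        }
        if self.pv is not None:
            out["EPSC_PV_pA"] = r5(self.pv.epsc_mean)
            out["IPSC_PV_pA"] = r5(self.pv.ipsc_mean)
        return out


@dataclass(frozen=True)
class ScenarioLabel:
    label: str  # "A", "B", or "indeterminate"


def detect_current_peaks(trace, record_dt: float, transient: float = 1000.0) -> np.ndarray:
    """Peak magnitudes (pA) of a signed PSC trace.

    The first ``transient`` ms are excluded; prominent local maxima of
    |trace| are found (minimum prominence one quarter of the trace range,
    the conventional default of interactive peak finders, so sub-peaks
    riding on a synaptic barrage are not counted separately) and peaks
    below one tenth of the global maximum are discarded.  An all-zero (or
    constant) trace yields an empty result.
    """
    trace = np.asarray(trace, float)
    n_skip = int(round(transient / record_dt))
    if trace.size <= n_skip:
        raise ValueError("trace shorter than the transient")
    x = np.abs(trace[n_skip:])
    if x.max() <= 0:
        return np.zeros(0)
    idx, _ = find_peaks(x, prominence=(x.max() - x.min()) / 4.0)
    if idx.size == 0:
        return np.zeros(0)
    peaks = x[idx]
    return peaks[peaks >= peaks.max() / 10.0]


def _per_cell_means(traces: np.ndarray, cols, record_dt: float,
                    transient: float) -> np.ndarray:
    out = []
    for c in cols:
        peaks = detect_current_peaks(traces[:, c], record_dt, transient)
        out.append(peaks.mean() if peaks.size else 0.0)
    return np.asarray(out)


def summarize_currents(
    result,
    rng: np.random.Generator | int | None = None,
    n_pyr_cells: int = N_ANALYZED_PYR,
    n_pv_cells: int = N_ANALYZED_PV,
) -> CurrentSummary:
    """Peak-EPSC/IPSC summary over a seeded choice of recorded cells.

    Per cell, peak magnitudes are averaged over the run (after the 1 s
    transient); the reported mean and SD are then taken across cells.
    Requires the run to have recorded at least the requested number of
    cells per class.
    """
    rng = np.random.default_rng(rng)
    transient = result.config.transient_currents

    def pick(pop: str, k: int):
        sl = result.record_columns.get(pop)
        if sl is None:
            if k > 0 and pop == "PYR":
                raise ValueError("run recorded no PYR traces")
            return None
        cols = np.arange(sl.start, sl.stop)
        if cols.size < k:
            raise ValueError(
                f"need {k} recorded {pop} cells, run recorded {cols.size}")
        return np.sort(rng.permutation(cols)[:k])

    pyr_cols = pick("PYR", n_pyr_cells)
    e = _per_cell_means(result.epsc, pyr_cols, result.record_dt, transient)
    i = _per_cell_means(result.ipsc, pyr_cols, result.record_dt, transient)
    pyr = PopulationCurrents(e.mean(), e.std(ddof=0), i.mean(), i.std(ddof=0))

    pv = None
    pv_cols = pick("PV", n_pv_cells) if "PV" in result.record_columns else None
    if pv_cols is not None:
        e = _per_cell_means(result.epsc, pv_cols, result.record_dt, transient)
        i = _per_cell_means(result.ipsc, pv_cols, result.record_dt, transient)
        pv = PopulationCurrents(e.mean(), e.std(ddof=0), i.mean(), i.std(ddof=0))
    return CurrentSummary(pyr=pyr, pv=pv,
                          n_pyr_cells=n_pyr_cells, n_pv_cells=n_pv_cells)


def classify_scenario(summary: CurrentSummary) -> ScenarioLabel:
    """Scenario label from the PV-cell E/I ratio alone.

    B when the ratio is close to or above 1 (>= 0.8), A when below;
    indeterminate when the PV IPSC is absent so no ratio exists.
    """
    if summary.pv is None or np.isnan(summary.pv.ei_ratio):
        return ScenarioLabel("indeterminate")
    return ScenarioLabel("B" if summary.pv.ei_ratio >= SCENARIO_B_RATIO else "A")


def check_experimental_consistency(summary: CurrentSummary) -> dict:
    """Compare a current summary against whole-hippocampus constraints.

    During intrinsic theta, PYR cells receive small EPSCs (< 20 pA) and
    ~200 pA IPSCs; PV+ cells receive large EPSCs (up to ~1000 pA) and
    ~200 pA IPSCs, so the PYR E/I ratio is < 1 and the PV E/I ratio > 1.
    The ~200 pA bands are applied as factor-of-3 intervals.
    """
    pyr, pv = summary.pyr, summary.pv
    flags = {
        "pyr_epsc_small": 0 < pyr.epsc_mean < 20.0,
        "pyr_ipsc_band": 200.0 / 3 <= pyr.ipsc_mean <= 200.0 * 3,
        "pyr_ratio_lt_1": (not np.isnan(pyr.ei_ratio)) and pyr.ei_ratio < 1.0,
    }
    if pv is None:
        flags.update(pv_epsc_bounded=False, pv_ipsc_band=False,
                     pv_ratio_gt_1=False)
    else:
        flags.update({
            "pv_epsc_bounded": 0 < pv.epsc_mean <= 1000.0,
            "pv_ipsc_band": 200.0 / 3 <= pv.ipsc_mean <= 200.0 * 3,
            "pv_ratio_gt_1": (not np.isnan(pv.ei_ratio)) and pv.ei_ratio > 1.0,
        })
    flags["consistent"] = all(flags.values())
    return flags
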