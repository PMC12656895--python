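"""Current-clamp protocols and validation metrics.

The protocols mirror the slice-physiology battery: a -5 pA x 500 ms step for
input resistance, 500 ms square pulses from 0 to 130 pA in 10 pA increments
for the F-I curve, and a 1 s ramp from 0 to 150 pA for the ramp current
threshold.  A spike is a local maximum strictly above 0 mV; successive
spikes must be separated by an upward re-crossing of -20 mV so that
subthreshold oscillations riding a depolarization-block plateau are not
counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cable import (
    CellState,
    DiscretizedCell,
    SimulationDiverged,
    SimulationSettings,
    StimulusProtocol,
)

__all__ = [
    "FI_GRID",
    "EXPERIMENTAL_FI_GRID",
    "MetricBundle",
    "detect_spikes",
    "input_resistance",
    "fi_curve",
    "ramp_threshold",
    "derive_summary",
    "classify_phenotype",
    "measure_metrics",
    "InvalidMeasurement",
]

#: Model F-I step grid: 0-130 pA in 10 pA increments (14 points).
FI_GRID = np.arange(0.0, 131.0, 10.0)
#: Experimental grid (0-140 pA) also supported for comparisons.
EXPERIMENTAL_FI_GRID = np.arange(0.0, 141.0, 10.0)

STEP_MS = 500.0
RAMP_MS = 1000.0
RAMP_MAX_PA = 150.0
SPIKE_PEAK_MV = 0.0
SPIKE_REARM_MV = -20.0
AP_THRESHOLD_DVDT = 10.0  # mV/ms

# classify_phenotype thresholds (fraction of peak rate at the final amplitude)
DB_FINAL_FRACTION = 0.5
NDB_FINAL_FRACTION = 0.8


class InvalidMeasurement(RuntimeError):
    """A protocol produced data the metric definition cannot use
    (e.g. the cell spiked during the hyperpolarizing probe)."""


@dataclass
class MetricBundle:
    """Validation metrics of one model.

    ``ramp_threshold_pA`` is ``None`` when the ramp elicits no spike.  ``ahp_mV``
    is measured on the rheobase trace and is ``None`` for nonspiking models.
    """

    input_resistance_MOhm: float
    fi_hz: np.ndarray
    fi_grid_pA: np.ndarray
    ramp_threshold_pA: float | None
    peak_firing_current_pA: float | None
    peak_firing_rate_hz: float
    rheobase_pA: float | None
    ahp_mV: float | None
    rmp_mV: float | None
    phenotype: str  # "DB" | "NDB" | "nonspiking"

    def is_complete(self) -> bool:
        """True when every score ingredient is defined (spiking model)."""
        return (
            self.phenotype != "nonspiking"
            and self.ramp_threshold_pA is not None
            and self.peak_firing_current_pA is not None
            and np.all(np.isfinite(self.fi_hz))
            and np.isfinite(self.input_resistance_MOhm)
        )


def detect_spikes(v: np.ndarray, dt_ms: float, t0_ms: float = 0.0) -> np.ndarray:
    """Spike times (ms) in a voltage trace.

    A spike is a local maximum strictly above 0 mV; after each accepted spike
    the detector re-arms only once the trace has dipped below -20 mV
    (upward re-crossing debounce).
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D voltage trace")
    if len(v) < 3:
        return np.empty(0)
    interior = v[1:-1]
    # strict on both sides: a numerically flat suprathreshold plateau (e.g.
    # a passive charging curve) is not a spike
    cand = np.where(
        (interior > SPIKE_PEAK_MV) & (interior > v[:-2]) & (interior > v[2:])
    )[0] + 1
    times = []
    last = None
    for i in cand:
        if last is None or v[last:i].min() < SPIKE_REARM_MV:
            times.append(t0_ms + i * dt_ms)
            last = i
    return np.asarray(times)


def _run_step(
    cell: DiscretizedCell,
    settings: SimulationSettings,
    state: CellState,
    amp_pA: float,
    dur_ms: float,
) -> np.ndarray:
    from . import _engine

    stim = np.full(int(round(dur_ms / settings.dt_ms)), float(amp_pA))
    rec, _, status = cell.run(stim, settings, state=state)
    if status != _engine.STATUS_OK:
        raise SimulationDiverged(f"divergence at {amp_pA} pA step")
    return rec


def input_resistance(
    cell: DiscretizedCell,
    settings: SimulationSettings,
    state: CellState | None = None,
    probe_pA: float = -5.0,
    window_ms: float = 50.0,
) -> float:
    """Steady-state input resistance (MOhm) from a small hyperpolarizing step.

    A ``probe_pA`` (default -5 pA) step is held for 500 ms from the
    equilibrated state; the voltage change is the mean over the final
    ``window_ms`` minus the pre-step baseline.  Spiking during the probe
    raises :class:`InvalidMeasurement`.
    """
    if state is None:
        state = cell.equilibrate(settings)
    dt = settings.dt_ms
    baseline = state.v[cell.soma_idx]
    rec = _run_step(cell, settings, state, probe_pA, STEP_MS)
    if len(detect_spikes(rec, dt)) > 0:
        raise InvalidMeasurement("cell spiked during the input-resistance probe")
    nwin = int(round(window_ms / dt))
    dv = rec[-nwin:].mean() - baseline
    rin = dv / probe_pA * 1e3  # mV/pA -> MOhm
    return rin


def fi_curve(
    cell: DiscretizedCell,
    settings: SimulationSettings,
    grid_pA: Sequence[float] = FI_GRID,
    state: CellState | None = None,
    return_traces: bool = False,
):
    """Firing rate (Hz) for each 500 ms square pulse on ``grid_pA``.

    Each amplitude starts from the same equilibrated state (the cell rests
    between sweeps).  Divergence at any amplitude marks the parameter set
    infeasible by raising :class:`SimulationDiverged`.
    """
    grid = np.asarray(grid_pA, dtype=float)
    if grid.size == 0:
        raise ValueError("F-I grid must be nonempty")
    if state is None:
        state = cell.equilibrate(settings)
    dt = settings.dt_ms
    rates = np.empty(len(grid))
    traces = []
    for k, amp in enumerate(grid):
        rec = _run_step(cell, settings, state, amp, STEP_MS)
        rates[k] = len(detect_spikes(rec, dt)) / (STEP_MS / 1e3)
        if return_traces:
            traces.append(rec)
    if return_traces:
        return rates, traces
    return rates


def ramp_threshold(
    cell: DiscretizedCell,
    settings: SimulationSettings,
    state: CellState | None = None,
    end_pA: float = RAMP_MAX_PA,
    duration_ms: float = RAMP_MS,
) -> float | None:
    """Injected current (pA) at the first spike of a 0->150 pA, 1 s ramp.

    Returns ``None`` (the no-spike sentinel) when the ramp elicits nothing.
    """
    if state is None:
        state = cell.equilibrate(settings)
    from . import _engine

    dt = settings.dt_ms
    n = int(round(duration_ms / dt))
    stim = end_pA * np.arange(n) * dt / duration_ms
    rec, _, status = cell.run(stim, settings, state=state)
    if status != _engine.STATUS_OK:
        raise SimulationDiverged("divergence during current ramp")
    spikes = detect_spikes(rec, dt)
    if len(spikes) == 0:
        return None
    return float(end_pA * spikes[0] / duration_ms)


def _ap_threshold_and_trough(v: np.ndarray, dt_ms: float) -> tuple[float, float] | None:
    """AP threshold (first dV/dt > 10 mV/ms) and post-spike trough of a trace."""
    dvdt = np.diff(v) / dt_ms
    above = np.where(dvdt > AP_THRESHOLD_DVDT)[0]
    if len(above) == 0:
        return None
    thr = v[above[0]]
    spikes = detect_spikes(v, dt_ms)
    if len(spikes) == 0:
        return None
    ipk = int(round(spikes[0] / dt_ms))
    trough = v[ipk:].min()
    return float(thr), float(trough)


def derive_summary(
    fi_hz: np.ndarray,
    grid_pA: np.ndarray,
    rheobase_trace: np.ndarray | None = None,
    dt_ms: float | None = None,
):
    """Summary metrics from an F-I curve.

    Returns ``(peak_firing_current, peak_firing_rate, rheobase, ahp)``.
    Peak firing current is the grid amplitude maximizing the rate (ties break
    to the lowest amplitude); rheobase is the lowest amplitude with at least
    one spike.  The AHP (threshold minus trough) requires the rheobase trace.
    All of the first three are ``None``/0 for a nonspiking curve.
    """
    fi_hz = np.asarray(fi_hz, dtype=float)
    grid_pA = np.asarray(grid_pA, dtype=float)
    if fi_hz.size == 0:
        raise ValueError("empty F-I curve")
    if not np.any(fi_hz > 0):
        return None, 0.0, None, None
    kmax = int(np.argmax(fi_hz))  # argmax returns the first (lowest) maximizer
    peak_current = float(grid_pA[kmax])
    peak_rate = float(fi_hz[kmax])
    rheo = float(grid_pA[np.nonzero(fi_hz > 0)[0][0]])
    ahp = None
    if rheobase_trace is not None and dt_ms is not None:
        tt = _ap_threshold_and_trough(rheobase_trace, dt_ms)
        if tt is not None:
            thr, trough = tt
            ahp = thr - trough
    return peak_current, peak_rate, rheo, ahp


def classify_phenotype(fi_hz: np.ndarray) -> str:
    """DB / NDB / nonspiking from the shape of the full-grid F-I curve.

    NDB: the rate at the maximum injected amplitude stays at >= 80% of the
    peak rate.  DB: it has fallen below 50% of the peak, and the peak occurs
    before the final amplitude.  The indeterminate band in between leans DB
    (partial entry into block).
    """
    fi_hz = np.asarray(fi_hz, dtype=float)
    if not np.any(fi_hz > 0):
        return "nonspiking"
    peak = fi_hz.max()
    final = fi_hz[-1]
    if final >= NDB_FINAL_FRACTION * peak:
        return "NDB"
    if final < DB_FINAL_FRACTION * peak and int(np.argmax(fi_hz)) < len(fi_hz) - 1:
        return "DB"
    return "DB"  # indeterminate band: DB-leaning


def measure_metrics(
    cell: DiscretizedCell,
    settings: SimulationSettings | None = None,
    grid_pA: Sequence[float] = FI_GRID,
    fail_fast: bool = False,
) -> MetricBundle:
    """Run the full validation battery on one cell.

    Equilibrates once and reuses that state for every protocol, mirroring
    rest periods between experimental sweeps.  Raises
    :class:`SimulationDiverged` if any protocol diverges.

    With ``fail_fast`` the ramp runs first and a cell that cannot spike even
    at the 150 pA ramp peak returns an incomplete (infinitely-scored) bundle
    without running the remaining protocols; the calibration scorer rejects
    such parameter sets either way, so this only saves simulation time.
    """
    if settings is None:
        settings = SimulationSettings()
    grid = np.asarray(grid_pA, dtype=float)
    state = cell.equilibrate(settings)
    rmp = float(state.v[cell.soma_idx])
    ramp = ramp_threshold(cell, settings, state=state)
    if fail_fast and ramp is None:
        return MetricBundle(
            input_resistance_MOhm=math.nan,
            fi_hz=np.zeros(len(grid)),
            fi_grid_pA=grid,
            ramp_threshold_pA=None,
            peak_firing_current_pA=None,
            peak_firing_rate_hz=0.0,
            rheobase_pA=None,
            ahp_mV=None,
            rmp_mV=rmp,
            phenotype="nonspiking",
        )
    try:
        rin = input_resistance(cell, settings, state=state)
    except InvalidMeasurement:
        rin = math.nan
    rates, traces = fi_curve(cell, settings, grid, state=state, return_traces=True)
    peak_current, peak_rate, rheo, ahp = derive_summary(rates, grid)
    if rheo is not None:
        k = int(np.nonzero(grid == rheo)[0][0])
        _, _, _, ahp = derive_summary(rates, grid, traces[k], settings.dt_ms)
    phen = classify_phenotype(rates)
    return MetricBundle(
        input_resistance_MOhm=float(rin),
        fi_hz=rates,
        fi_grid_pA=grid,
        ramp_threshold_pA=ramp,
        peak_firing_current_pA=peak_current,
        peak_firing_rate_hz=peak_rate,
        rheobase_pA=rheo,
        ahp_mV=ahp,
        rmp_mV=rmp,
        phenotype=phen,
    )
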