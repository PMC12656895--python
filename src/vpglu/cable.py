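"""Ball-and-stick-plus-myelinated-axon cable model of a VP glutamatergic neuron.

The compartment chain runs dendrite (distal tip first) -> soma -> axon
hillock -> axon (nodes of Ranvier alternating with myelinated internodes,
node first and node last).  The default morphology is a 10x10 um soma, a
30 um x 1 um hillock carrying the eight active channels, a single
1371 um x 0.3 um passive dendrite, and 100 nodes / 99 internodes.

Only the hillock is active (8 channels + leak); nodes carry squid-type
Hodgkin-Huxley kinetics; soma, dendrite, and internodes are passive cables.
Voltages are integrated with backward Euler on the tridiagonal cable system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from . import _engine
from .channels import (
    ChannelSet,
    ConductanceVector,
    PackedChannels,
    equilibrium_bound_fraction,
    load_default_channels,
    pack_channels,
    pack_node_hh,
)

__all__ = [
    "Section",
    "Morphology",
    "PassiveProperties",
    "NodeHH",
    "ShellParams",
    "PVParams",
    "SimulationSettings",
    "VoltageTrace",
    "StimulusProtocol",
    "DiscretizedCell",
    "SimulationDiverged",
    "build_morphology",
    "discretize",
    "simulate",
    "DEFAULT_MORPHOLOGY_CONFIG",
]

SECTION_KINDS = ("soma", "hillock", "dendrite", "node", "internode")


class SimulationDiverged(RuntimeError):
    """Raised when the membrane potential leaves the plausible range.

    The calibration scorer treats this as an infeasible parameter set."""


@dataclass(frozen=True)
class Section:
    name: str
    kind: str
    length_um: float
    diam_um: float
    nseg: int

    def __post_init__(self):
        if self.kind not in SECTION_KINDS:
            raise ValueError(f"unknown section kind {self.kind!r}")
        if self.length_um <= 0 or self.diam_um <= 0:
            raise ValueError(f"section {self.name}: length and diameter must be > 0")
        if self.nseg < 1:
            raise ValueError(f"section {self.name}: nseg must be >= 1")


@dataclass(frozen=True)
class Morphology:
    """Ordered sections of the compartment chain (dendrite-side first)."""

    sections: tuple[Section, ...]
    axon_node_count: int
    axon_internode_count: int

    def __post_init__(self):
        if self.axon_node_count < 1:
            raise ValueError("axon must have at least one node of Ranvier")
        if self.axon_internode_count != self.axon_node_count - 1:
            raise ValueError("axon must alternate node-first: internodes = nodes - 1")

    def section(self, name: str) -> Section:
        for s in self.sections:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def n_compartments(self) -> int:
        return sum(s.nseg for s in self.sections)


#: Default morphology: dimensions of the experimental target cell class.
DEFAULT_MORPHOLOGY_CONFIG: dict = {
    "soma": {"length_um": 10.0, "diam_um": 10.0, "nseg": 1},
    "hillock": {"length_um": 30.0, "diam_um": 1.0, "nseg": 3},
    "dendrite": {"length_um": 1371.0, "diam_um": 0.3, "nseg": 41},
    "node": {"length_um": 1.0, "diam_um": 1.0, "nseg": 1},
    "internode": {"length_um": 100.0, "diam_um": 1.0, "nseg": 1},
    "axon_node_count": 100,
}


def build_morphology(config: Mapping | None = None) -> Morphology:
    """Build the five-region morphology; defaults give the standard cell.

    ``config`` may override any of the section entries (length_um, diam_um,
    nseg) or ``axon_node_count``.  Validation errors are raised for
    non-positive dimensions or node counts.
    """
    cfg = {k: dict(v) if isinstance(v, Mapping) else v for k, v in DEFAULT_MORPHOLOGY_CONFIG.items()}
    if config:
        for k, v in config.items():
            if k == "axon_node_count":
                cfg[k] = int(v)
            elif k in cfg:
                cfg[k].update(v)
            else:
                raise ValueError(f"unknown morphology key {k!r}")
    n_nodes = int(cfg["axon_node_count"])
    if n_nodes < 1:
        raise ValueError("axon_node_count must be >= 1")
    secs = [Section(name="dendrite", kind="dendrite", **cfg["dendrite"])]
    secs.append(Section(name="soma", kind="soma", **cfg["soma"]))
    secs.append(Section(name="hillock", kind="hillock", **cfg["hillock"]))
    for i in range(n_nodes):
        secs.append(Section(name=f"node[{i}]", kind="node", **cfg["node"]))
        if i < n_nodes - 1:
            secs.append(Section(name=f"internode[{i}]", kind="internode", **cfg["internode"]))
    return Morphology(
        sections=tuple(secs),
        axon_node_count=n_nodes,
        axon_internode_count=n_nodes - 1,
    )


@dataclass(frozen=True)
class PassiveProperties:
    """Passive membrane and axial parameters, per section kind.

    ``leak_conductance`` entries of ``None`` mean the compartment's leak is
    set from the free parameter vector (the 9th calibration parameter applies
    uniformly to soma, dendrite, and hillock).  Node leak lives inside the
    nodal HH mechanism, so the node entry here is 0 by default.
    """

    membrane_capacitance: Mapping[str, float] = field(
        default_factory=lambda: {
            "soma": 1.0, "hillock": 1.0, "dendrite": 1.0, "node": 1.0, "internode": 0.04,
        }
    )
    axial_resistivity: float = 150.0  # Ohm cm
    leak_conductance: Mapping[str, float | None] = field(
        default_factory=lambda: {
            "soma": None, "hillock": None, "dendrite": None, "node": 0.0, "internode": 1e-5,
        }
    )
    leak_reversal: Mapping[str, float] = field(
        default_factory=lambda: {
            "soma": -60.0, "hillock": -60.0, "dendrite": -60.0, "node": -60.0, "internode": -60.0,
        }
    )

    def __post_init__(self):
        if self.axial_resistivity <= 0:
            raise ValueError("axial resistivity must be > 0")
        for k in SECTION_KINDS:
            if self.membrane_capacitance[k] <= 0:
                raise ValueError(f"capacitance for {k} must be > 0")
            g = self.leak_conductance[k]
            if g is not None and g < 0:
                raise ValueError(f"leak conductance for {k} must be >= 0")


@dataclass(frozen=True)
class NodeHH:
    """Squid-type HH mechanism of the nodes of Ranvier (conductances S/cm2)."""

    g_na: float = 0.12
    g_k: float = 0.036
    g_leak: float = 3e-4
    e_na: float = 50.0
    e_k: float = -77.0
    e_leak: float = -54.3


@dataclass(frozen=True)
class ShellParams:
    """Submembrane calcium shell in the hillock compartments."""

    depth_um: float = 0.1
    baseline_mM: float = 5e-5
    tau_ms: float = 20.0


@dataclass(frozen=True)
class PVParams:
    """Parvalbumin buffer: total concentration and mass-action rates."""

    total_mM: float = 0.0
    k_on: float = 40.0   # 1/(mM ms)
    k_off: float = 2e-4  # 1/ms


@dataclass(frozen=True)
class SimulationSettings:
    """Integration settings: 25 us backward-Euler steps, -60 mV init, 23 C,
    500 ms equilibration before any stimulus."""

    dt_ms: float = 0.025
    v_init: float = -60.0
    temperature_C: float = 23.0
    equilibration_ms: float = 500.0
    q10_factor: float = 1.0  # kinetics taken as defined at nominal temperature

    def __post_init__(self):
        if self.dt_ms <= 0:
            raise ValueError("dt must be > 0")
        if self.equilibration_ms < 0:
            raise ValueError("equilibration must be >= 0")


@dataclass(frozen=True)
class StimulusProtocol:
    """Somatic current-clamp stimulus.

    kind ``step`` holds ``amplitude_pA`` for ``duration_ms``; ``ramp`` sweeps
    linearly from ``start_pA`` to ``end_pA``; ``hold`` injects nothing.
    ``onset_ms`` delays the stimulus after the equilibration period.
    """

    kind: str = "step"
    amplitude_pA: float = 0.0
    start_pA: float = 0.0
    end_pA: float = 0.0
    duration_ms: float = 500.0
    onset_ms: float = 0.0

    def __post_init__(self):
        if self.kind not in ("step", "ramp", "hold"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.duration_ms <= 0:
            raise ValueError("duration must be > 0")
        if self.onset_ms < 0:
            raise ValueError("onset must be >= 0")

    def samples(self, dt_ms: float) -> np.ndarray:
        """Injected current (pA) at each integration step of the protocol window."""
        n_on = int(round(self.onset_ms / dt_ms))
        n_dur = int(round(self.duration_ms / dt_ms))
        out = np.zeros(n_on + n_dur)
        if self.kind == "step":
            out[n_on:] = self.amplitude_pA
        elif self.kind == "ramp":
            tt = np.arange(n_dur) * dt_ms
            out[n_on:] = self.start_pA + (self.end_pA - self.start_pA) * tt / self.duration_ms
        if not np.all(np.isfinite(out)):
            raise ValueError("protocol current must be finite")
        return out


@dataclass
class VoltageTrace:
    """Somatic recording: uniform time grid (ms), V (mV), injected I (pA)."""

    t: np.ndarray
    v: np.ndarray
    i: np.ndarray
    dt_ms: float
    equilibration_ms: float = 0.0

    def __post_init__(self):
        if not (len(self.t) == len(self.v) == len(self.i)):
            raise ValueError("time, voltage, and current arrays must align")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_ms": self.t, "v_mV": self.v, "i_pA": self.i})


@dataclass
class CellState:
    """Full dynamical state of a discretized cell."""

    v: np.ndarray       # (n,)
    gates_h: np.ndarray  # (nh, ng)
    gates_n: np.ndarray  # (n_nodes, 3)
    ca: np.ndarray      # (nh,)
    ca_bound: np.ndarray  # (nh,)

    def copy(self) -> "CellState":
        return CellState(
            self.v.copy(), self.gates_h.copy(), self.gates_n.copy(),
            self.ca.copy(), self.ca_bound.copy(),
        )


class DiscretizedCell:
    """Compartmentalized cell with packed arrays for the compiled integrator."""

    def __init__(
        self,
        morphology: Morphology,
        passive: PassiveProperties,
        theta: ConductanceVector,
        channels: ChannelSet | None = None,
        node_hh: NodeHH | None = None,
        shell: ShellParams | None = None,
        pv: PVParams | None = None,
    ):
        self.morphology = morphology
        self.passive = passive
        self.theta = theta
        self.channels = channels if channels is not None else load_default_channels()
        self.node_hh = node_hh if node_hh is not None else NodeHH()
        self.shell = shell if shell is not None else ShellParams()
        self.pv = pv if pv is not None else PVParams()
        self._pack_cache: dict = {}
        self._build_arrays()

    # -- construction ----------------------------------------------------
    def _build_arrays(self) -> None:
        m, p = self.morphology, self.passive
        th = self.theta.as_array()
        areas, cms, gls, els, kinds, rhalf = [], [], [], [], [], []
        node_idx, hil_idx = [], []
        i = 0
        for sec in m.sections:
            seg_l = sec.length_um / sec.nseg
            area = math.pi * sec.diam_um * seg_l * 1e-8  # cm2 (cylinder side wall)
            # axial half-resistance of one segment, Ohm
            radius_cm = sec.diam_um / 2.0 * 1e-4
            rh = p.axial_resistivity * (seg_l / 2.0 * 1e-4) / (math.pi * radius_cm**2)
            gl = p.leak_conductance[sec.kind]
            if gl is None:
                gl = th[8]
            for _ in range(sec.nseg):
                areas.append(area)
                cms.append(p.membrane_capacitance[sec.kind])
                gls.append(gl)
                els.append(p.leak_reversal[sec.kind])
                kinds.append(sec.kind)
                rhalf.append(rh)
                if sec.kind == "node":
                    node_idx.append(i)
                elif sec.kind == "hillock":
                    hil_idx.append(i)
                i += 1
        n = i
        self.n_compartments = n
        self.area = np.array(areas)
        self.cm = np.array(cms)
        self.gpas = np.array(gls)
        self.epas = np.array(els)
        self.gepas = self.gpas * self.epas
        self.kinds = kinds
        rhalf = np.array(rhalf)
        self.gax = 1.0 / (rhalf[:-1] + rhalf[1:])  # S, between i and i+1
        self.node_idx = np.array(node_idx, dtype=np.int64)
        if not hil_idx:
            raise ValueError("morphology has no hillock compartments")
        self.hil0 = hil_idx[0]
        self.nh = len(hil_idx)
        # soma compartment: middle of the (single- or multi-segment) soma
        soma_comps = [j for j, k in enumerate(kinds) if k == "soma"]
        if not soma_comps:
            raise ValueError("morphology has no soma")
        self.soma_idx = soma_comps[len(soma_comps) // 2]
        self.g_hillock = th[:8].copy()

    # -- state -----------------------------------------------------------
    def init_state(self, settings: SimulationSettings) -> CellState:
        v0 = settings.v_init
        packed = self._packed(settings)
        v = np.full(self.n_compartments, v0)
        ca0 = self.shell.baseline_mM
        flat_gates = [g for ch in self.channels for g in ch.gates]
        assert len(flat_gates) == packed.n_gates
        gh = np.zeros((self.nh, len(flat_gates)))
        for gi, gate in enumerate(flat_gates):
            gh[:, gi] = gate.steady_state(v0, ca0)
        from .channels import hh_steady_tau

        (mi, hi, ni), _ = hh_steady_tau(v0, settings.q10_factor)
        gn = np.tile(np.array([mi, hi, ni]), (len(self.node_idx), 1))
        ca = np.full(self.nh, ca0)
        bound0 = self.pv.total_mM * equilibrium_bound_fraction(ca0, self.pv.k_on, self.pv.k_off)
        cab = np.full(self.nh, bound0)
        return CellState(v=v, gates_h=gh, gates_n=gn, ca=ca, ca_bound=cab)

    def _packed(self, settings: SimulationSettings) -> PackedChannels:
        key = (settings.dt_ms, settings.q10_factor)
        if key not in self._pack_cache:
            pc = pack_channels(self.channels, settings.dt_ms)
            inf_n, qfac_n = pack_node_hh(
                settings.dt_ms, pc.v_min, pc.v_min + pc.dv * (pc.n_v - 1), pc.dv,
                settings.q10_factor,
            )
            self._pack_cache[key] = (pc, inf_n, qfac_n)
        return self._pack_cache[key][0]

    # -- integration -----------------------------------------------------
    def run(
        self,
        stim_pA: np.ndarray,
        settings: SimulationSettings,
        state: CellState | None = None,
    ) -> tuple[np.ndarray, CellState, int]:
        """Advance the cell through ``stim_pA`` (one value per time step).

        Returns ``(somatic V per step, final state, status)``.  The input
        state is not modified; pass the returned state to continue a run.
        """
        pc, inf_n, qfac_n = self._pack_cache.get(
            (settings.dt_ms, settings.q10_factor)
        ) or (None, None, None)
        if pc is None:
            self._packed(settings)
            pc, inf_n, qfac_n = self._pack_cache[(settings.dt_ms, settings.q10_factor)]
        if state is None:
            state = self.init_state(settings)
        st = state.copy()
        stim = np.ascontiguousarray(stim_pA, dtype=float)
        rec = np.empty(len(stim))
        dt = settings.dt_ms
        cdt = 1e-3 * self.cm * self.area / dt
        nhh = self.node_hh
        status = _engine.step_loop(
            st.v, st.gates_h, st.gates_n, st.ca, st.ca_bound,
            stim, rec, dt,
            cdt, self.area, self.gax, self.gpas, self.gepas,
            self.soma_idx, self.hil0, self.nh, self.node_idx,
            self.g_hillock,
            pc.erev, pc.is_ca,
            pc.gate_channel, pc.gate_exp, pc.gate_kind,
            pc.inf_tab, pc.qfac_tab, pc.v_min, 1.0 / pc.dv, pc.n_v,
            pc.ca_kd, pc.ca_hill, pc.ca_qfac,
            pc.bk_vhalf, pc.bk_slope, pc.bk_shift, pc.bk_lg_caref,
            nhh.g_na, nhh.g_k, nhh.g_leak, nhh.e_na, nhh.e_k, nhh.e_leak,
            inf_n, qfac_n,
            self.shell.depth_um, self.shell.baseline_mM, self.shell.tau_ms,
            self.pv.total_mM, self.pv.k_on, self.pv.k_off,
        )
        return rec, st, status

    def equilibrate(self, settings: SimulationSettings) -> CellState:
        """Rest the cell for the configured equilibration period (no stimulus)."""
        n = int(round(settings.equilibration_ms / settings.dt_ms))
        _, st, status = self.run(np.zeros(n), settings)
        if status != _engine.STATUS_OK:
            raise SimulationDiverged("cell diverged during equilibration")
        return st

    def with_pv(self, total_mM: float) -> "DiscretizedCell":
        """Same cell with a different total parvalbumin concentration."""
        return DiscretizedCell(
            self.morphology, self.passive, self.theta, self.channels,
            self.node_hh, self.shell, replace(self.pv, total_mM=total_mM),
        )


def discretize(
    morphology: Morphology,
    passive: PassiveProperties,
    theta: ConductanceVector,
    **kwargs,
) -> DiscretizedCell:
    """Discretize a morphology into a runnable compartment chain."""
    return DiscretizedCell(morphology, passive, theta, **kwargs)


def simulate(
    cell: DiscretizedCell,
    protocol: StimulusProtocol,
    settings: SimulationSettings,
    state: CellState | None = None,
) -> VoltageTrace:
    """Run equilibration followed by ``protocol``; return the somatic trace.

    If ``state`` is supplied the equilibration phase is skipped and the
    protocol starts from that state (the trace then covers the protocol
    only).  Numerical divergence raises :class:`SimulationDiverged`.
    """
    dt = settings.dt_ms
    if state is None:
        n_eq = int(round(settings.equilibration_ms / dt))
        stim = np.concatenate([np.zeros(n_eq), protocol.samples(dt)])
        equil_ms = settings.equilibration_ms
        v0 = settings.v_init
        rec, _, status = cell.run(stim, settings)
    else:
        stim = protocol.samples(dt)
        equil_ms = 0.0
        v0 = state.v[cell.soma_idx]
        rec, _, status = cell.run(stim, settings, state=state)
    if status != _engine.STATUS_OK:
        raise SimulationDiverged(
            f"membrane potential diverged under {protocol.kind} protocol"
        )
    n = len(stim)
    t = np.arange(n + 1) * dt
    v = np.concatenate([[v0], rec])
    i = np.concatenate([stim, [stim[-1]]])
    return VoltageTrace(t=t, v=v, i=i, dt_ms=dt, equilibration_ms=equil_ms)
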