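"""Ion-channel gating kinetics, intracellular calcium, and the parvalbumin buffer.

The eight active channels expressed in the axon hillock (Nav1.6, delayed
rectifier, A-type, SK, BK, M-type, L-type Ca, T-type Ca) are described by
parameter tables shipped as YAML files under ``vpglu/data/channels``.  Each
gate is one of three kinds:

``voltage``
    Boltzmann steady state ``x_inf = 1/(1+exp(-(V-Vh)/k))`` (k < 0 for
    inactivation gates) with a bell-shaped voltage-dependent time constant
    ``tau = tau_min + tau_amp/(exp((V-Vp)/kl) + exp(-(V-Vp)/kr))``.
``calcium``
    Hill activation on submembrane free calcium,
    ``x_inf = Ca^h/(Ca^h + Kd^h)``, fixed time constant (SK).
``voltage_cashift``
    Boltzmann in V whose midpoint shifts leftward with calcium,
    ``Vh(Ca) = Vh0 - s*log10(Ca/Ca_ref)`` (BK).

Free intracellular calcium lives in a thin submembrane shell with linear
extrusion back to baseline; parvalbumin binds free calcium by mass action
(``d[CaPV]/dt = k_on [Ca]([PV]_tot - [CaPV]) - k_off [CaPV]``).  Magnesium
competition for the parvalbumin sites is deliberately not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "PARAM_NAMES",
    "ConductanceVector",
    "GateSpec",
    "GatingScheme",
    "ChannelSet",
    "CalciumState",
    "PVBufferState",
    "load_default_channels",
    "gate_dynamics",
    "total_ionic_current",
    "update_calcium",
    "update_pv_buffer",
    "equilibrium_bound_fraction",
]

#: Order of the nine free parameters explored by the calibration: eight
#: maximal active conductances plus the passive leak conductance (all S/cm2).
PARAM_NAMES = (
    "g_nav16",
    "g_kdr",
    "g_ka",
    "g_sk",
    "g_bk",
    "g_km",
    "g_cal",
    "g_cat",
    "g_leak",
)

CHANNEL_ORDER = ("nav16", "kdr", "ka", "sk", "bk", "km", "cal", "cat")

GATE_VOLTAGE = 0
GATE_CALCIUM = 1
GATE_CASHIFT = 2

_KIND_CODES = {"voltage": GATE_VOLTAGE, "calcium": GATE_CALCIUM, "voltage_cashift": GATE_CASHIFT}


@dataclass(frozen=True)
class ConductanceVector:
    """The 9 free parameters (S/cm2): 8 hillock maximal conductances + leak."""

    g_nav16: float
    g_kdr: float
    g_ka: float
    g_sk: float
    g_bk: float
    g_km: float
    g_cal: float
    g_cat: float
    g_leak: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "ConductanceVector":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (9,):
            raise ValueError(f"expected 9 parameters, got shape {theta.shape}")
        return cls(*theta)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    def replace(self, **kw) -> "ConductanceVector":
        return replace(self, **kw)


@dataclass(frozen=True)
class GateSpec:
    """One gating variable of a channel."""

    name: str
    exponent: int
    kind: int  # GATE_VOLTAGE / GATE_CALCIUM / GATE_CASHIFT
    # voltage / voltage_cashift parameters
    vhalf: float = 0.0
    slope: float = 1.0
    tau_min: float = 1.0
    tau_amp: float = 0.0
    tau_vpeak: float = 0.0
    tau_kleft: float = 20.0
    tau_kright: float = 20.0
    # calcium-gate parameters
    kd: float = 1e-3
    hill: float = 1.0
    tau_ca: float = 1.0
    # cashift parameters
    shift_per_decade: float = 0.0
    ca_ref: float = 1e-3

    def steady_state(self, v: float, ca: float) -> float:
        if self.kind == GATE_CALCIUM:
            r = (max(ca, 1e-12) / self.kd) ** self.hill
            return r / (1.0 + r)
        vh = self.vhalf
        if self.kind == GATE_CASHIFT:
            vh = vh - self.shift_per_decade * math.log10(max(ca, 1e-9) / self.ca_ref)
        return 1.0 / (1.0 + math.exp(-(v - vh) / self.slope))

    def time_constant(self, v: float) -> float:
        if self.kind == GATE_CALCIUM:
            return self.tau_ca
        den = math.exp((v - self.tau_vpeak) / self.tau_kleft) + math.exp(
            -(v - self.tau_vpeak) / self.tau_kright
        )
        return self.tau_min + self.tau_amp / den


@dataclass(frozen=True)
class GatingScheme:
    """A channel: named gates, reversal potential, calcium-carrying flag."""

    name: str
    conductance_param: str
    reversal: float  # mV
    carries_calcium: bool
    gates: tuple[GateSpec, ...]

    def validate(self, v_grid: np.ndarray | None = None) -> None:
        """Check gate invariants: steady states in [0,1], tau > 0 on [-120, 60] mV."""
        if v_grid is None:
            v_grid = np.linspace(-120.0, 60.0, 181)
        for g in self.gates:
            for v in v_grid:
                ss = g.steady_state(float(v), 1e-4)
                if not (0.0 <= ss <= 1.0):
                    raise ValueError(f"{self.name}.{g.name}: steady state {ss} outside [0,1]")
                if g.time_constant(float(v)) <= 0:
                    raise ValueError(f"{self.name}.{g.name}: non-positive time constant")


def _parse_gate(d: dict) -> GateSpec:
    kind = _KIND_CODES[d["kind"]]
    kw: dict = dict(name=d["name"], exponent=int(d["exponent"]), kind=kind)
    if kind == GATE_CALCIUM:
        act = d["activation"]
        kw.update(kd=float(act["kd_mM"]), hill=float(act["hill"]), tau_ca=float(act["tau_ms"]))
    else:
        inf = d["inf"]
        kw.update(vhalf=float(inf["vhalf_mV"]), slope=float(inf["slope_mV"]))
        if kind == GATE_CASHIFT:
            kw.update(
                shift_per_decade=float(inf["shift_mV_per_decade"]),
                ca_ref=float(inf["ca_ref_mM"]),
            )
        tau = d["tau"]
        kw.update(
            tau_min=float(tau["min_ms"]),
            tau_amp=float(tau["amp_ms"]),
            tau_vpeak=float(tau["vpeak_mV"]),
            tau_kleft=float(tau["kleft_mV"]),
            tau_kright=float(tau["kright_mV"]),
        )
    return GateSpec(**kw)


def load_channel(source) -> GatingScheme:
    """Load one channel description from a YAML mapping, path, or file object."""
    if isinstance(source, dict):
        d = source
    else:
        with open(source) as fh:
            d = yaml.safe_load(fh)
    scheme = GatingScheme(
        name=d["name"],
        conductance_param=d["conductance_param"],
        reversal=float(d["reversal_mV"]),
        carries_calcium=bool(d.get("carries_calcium", False)),
        gates=tuple(_parse_gate(g) for g in d["gates"]),
    )
    scheme.validate()
    return scheme


@dataclass(frozen=True)
class ChannelSet:
    """The eight hillock channels in canonical order."""

    channels: tuple[GatingScheme, ...]

    def __post_init__(self):
        names = tuple(c.name for c in self.channels)
        if names != CHANNEL_ORDER:
            raise ValueError(f"channels must be in canonical order {CHANNEL_ORDER}, got {names}")

    def __iter__(self):
        return iter(self.channels)

    def __getitem__(self, name: str) -> GatingScheme:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(name)

    def with_channel(self, scheme: GatingScheme) -> "ChannelSet":
        return ChannelSet(tuple(scheme if c.name == scheme.name else c for c in self.channels))


def load_default_channels() -> ChannelSet:
    """Load the packaged default kinetics tables."""
    out = []
    pkg = resources.files("vpglu.data.channels")
    for name in CHANNEL_ORDER:
        with (pkg / f"{name}.yaml").open() as fh:
            out.append(load_channel(yaml.safe_load(fh)))
    return ChannelSet(tuple(out))


def gate_dynamics(channel: GatingScheme, v: float, ca: float = 1e-4):
    """Steady states and time constants of every gate of ``channel`` at (V, Ca).

    Returns two dicts keyed by gate name: ``(steady_states, time_constants)``.
    """
    if not np.isfinite(v):
        raise ValueError("V must be finite")
    ss = {g.name: g.steady_state(v, ca) for g in channel.gates}
    tau = {g.name: g.time_constant(v) for g in channel.gates}
    return ss, tau


def total_ionic_current(
    theta: ConductanceVector,
    gates: dict[str, dict[str, float]],
    v: float,
    ca: float,
    channels: ChannelSet | None = None,
    e_leak: float = -60.0,
) -> dict[str, float]:
    """Total membrane current density (mA/cm2) split per channel plus leak.

    ``gates`` maps channel name -> {gate name -> open fraction}.  Each channel
    contributes the ohmic term ``gbar * prod(x^p) * (V - E)``; the returned
    dict carries one entry per channel, ``"leak"``, and ``"total"``.
    """
    if channels is None:
        channels = load_default_channels()
    th = theta.as_array()
    out: dict[str, float] = {}
    total = 0.0
    for i, ch in enumerate(channels):
        prod = 1.0
        for g in ch.gates:
            x = gates[ch.name][g.name]
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"gate {ch.name}.{g.name} out of [0,1]: {x}")
            prod *= x**g.exponent
        cur = th[i] * prod * (v - ch.reversal)
        out[ch.name] = cur
        total += cur
    leak = th[8] * (v - e_leak)
    out["leak"] = leak
    out["total"] = total + leak
    return out


# ---------------------------------------------------------------------------
# calcium dynamics and the parvalbumin buffer

FARADAY = 96485.332  # C/mol


@dataclass(frozen=True)
class CalciumState:
    """Free calcium in a submembrane shell (all concentrations in mM)."""

    free: float = 5e-5
    depth_um: float = 0.1
    baseline: float = 5e-5
    tau_ms: float = 20.0

    def __post_init__(self):
        if self.free < 0 or self.baseline < 0:
            raise ValueError("calcium concentrations must be >= 0")
        if self.depth_um <= 0 or self.tau_ms <= 0:
            raise ValueError("shell depth and extrusion tau must be > 0")


@dataclass(frozen=True)
class PVBufferState:
    """Parvalbumin pool: total and calcium-bound concentration (mM)."""

    total: float = 0.0
    bound: float = 0.0
    k_on: float = 40.0  # 1/(mM ms)
    k_off: float = 2e-4  # 1/ms  (Kd = k_off/k_on = 5 nM)

    def __post_init__(self):
        if not (0.0 <= self.bound <= self.total + 1e-15):
            raise ValueError("bound PV must lie in [0, total]")
        if self.k_on <= 0 or self.k_off < 0:
            raise ValueError("rate constants must be positive")

    @property
    def kd(self) -> float:
        return self.k_off / self.k_on


def equilibrium_bound_fraction(ca: float, k_on: float, k_off: float) -> float:
    """Equilibrium fraction of PV sites occupied at clamped free calcium."""
    kd = k_off / k_on
    return ca / (ca + kd)


def calcium_influx_rate(i_ca: float, depth_um: float) -> float:
    """Shell filling rate (mM/ms) from a calcium current density (mA/cm2).

    Inward calcium current is negative by convention, so the returned rate is
    positive for influx: ``J = -1e4 * I_Ca / (2 F depth)`` with depth in um.
    """
    return -1e4 * i_ca / (2.0 * FARADAY * depth_um)


def update_calcium(state: CalciumState, i_ca: float, dt: float) -> CalciumState:
    """One backward-Euler step of shell calcium: influx + linear extrusion."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    j = calcium_influx_rate(i_ca, state.depth_um)
    r = dt / state.tau_ms
    free = (state.free + dt * j + r * state.baseline) / (1.0 + r)
    return replace(state, free=max(free, 0.0))


def _exchange_step(free: float, bound: float, total: float, k_on: float, k_off: float, dt: float):
    """Backward-Euler mass-action exchange between free Ca and PV; conserves Ca."""
    if total <= 0.0:
        return free, bound
    k1 = dt * k_on
    k2 = dt * k_off
    s = free + bound
    beta = 1.0 + k2 + k1 * (total - s)
    gamma = s * (1.0 + k2) - bound
    c1 = (math.sqrt(beta * beta + 4.0 * k1 * gamma) - beta) / (2.0 * k1)
    b1 = s - c1
    return c1, b1


def update_pv_buffer(ca: CalciumState, pv: PVBufferState, dt: float):
    """One backward-Euler step of Ca<->PV mass-action binding.

    Calcium bound during the step is removed from the free pool; the update
    conserves free + bound exactly (to round-off).  Returns the new
    ``(CalciumState, PVBufferState)`` pair.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    free, bound = _exchange_step(ca.free, pv.bound, pv.total, pv.k_on, pv.k_off, dt)
    return replace(ca, free=free), replace(pv, bound=bound)


# ---------------------------------------------------------------------------
# packing for the compiled integrator

@dataclass(frozen=True)
class PackedChannels:
    """Flat array view of a ChannelSet, tabulated on a voltage grid.

    ``qfac`` tables store ``1 - exp(-dt/tau)`` so the integrator advances each
    gate by an exact exponential update with two table lookups; they are
    therefore specific to one time step.
    """

    dt: float
    v_min: float
    dv: float
    n_v: int
    gate_channel: np.ndarray  # (ng,) int64
    gate_exp: np.ndarray  # (ng,) int64
    gate_kind: np.ndarray  # (ng,) int64
    inf_tab: np.ndarray  # (ng, nv)
    qfac_tab: np.ndarray  # (ng, nv)
    ca_kd: np.ndarray  # (ng,)
    ca_hill: np.ndarray  # (ng,)
    ca_qfac: np.ndarray  # (ng,)
    bk_vhalf: np.ndarray  # (ng,)
    bk_slope: np.ndarray  # (ng,)
    bk_shift: np.ndarray  # (ng,)
    bk_lg_caref: np.ndarray  # (ng,) log10 of ca_ref
    erev: np.ndarray  # (nc,)
    is_ca: np.ndarray  # (nc,) int64
    n_gates: int
    n_channels: int


def pack_channels(
    channels: ChannelSet,
    dt: float,
    v_min: float = -150.0,
    v_max: float = 80.0,
    dv: float = 0.05,
) -> PackedChannels:
    """Tabulate a ChannelSet for the compiled integrator at time step ``dt`` (ms)."""
    gates: list[tuple[int, GateSpec]] = []
    for ci, ch in enumerate(channels):
        for g in ch.gates:
            gates.append((ci, g))
    ng = len(gates)
    nv = int(round((v_max - v_min) / dv)) + 1
    v = v_min + dv * np.arange(nv)

    inf_tab = np.zeros((ng, nv))
    qfac_tab = np.zeros((ng, nv))
    gate_channel = np.zeros(ng, dtype=np.int64)
    gate_exp = np.zeros(ng, dtype=np.int64)
    gate_kind = np.zeros(ng, dtype=np.int64)
    ca_kd = np.ones(ng)
    ca_hill = np.ones(ng)
    ca_qfac = np.zeros(ng)
    bk_vhalf = np.zeros(ng)
    bk_slope = np.ones(ng)
    bk_shift = np.zeros(ng)
    bk_lg_caref = np.zeros(ng)

    for gi, (ci, g) in enumerate(gates):
        gate_channel[gi] = ci
        gate_exp[gi] = g.exponent
        gate_kind[gi] = g.kind
        if g.kind == GATE_CALCIUM:
            ca_kd[gi] = g.kd
            ca_hill[gi] = g.hill
            ca_qfac[gi] = 1.0 - math.exp(-dt / g.tau_ca)
        else:
            tau = np.array([g.time_constant(float(vv)) for vv in v])
            qfac_tab[gi] = 1.0 - np.exp(-dt / tau)
            if g.kind == GATE_CASHIFT:
                bk_vhalf[gi] = g.vhalf
                bk_slope[gi] = g.slope
                bk_shift[gi] = g.shift_per_decade
                bk_lg_caref[gi] = math.log10(g.ca_ref)
            else:
                inf_tab[gi] = np.array([g.steady_state(float(vv), 0.0) for vv in v])

    erev = np.array([c.reversal for c in channels])
    is_ca = np.array([1 if c.carries_calcium else 0 for c in channels], dtype=np.int64)
    return PackedChannels(
        dt=dt,
        v_min=v_min,
        dv=dv,
        n_v=nv,
        gate_channel=gate_channel,
        gate_exp=gate_exp,
        gate_kind=gate_kind,
        inf_tab=inf_tab,
        qfac_tab=qfac_tab,
        ca_kd=ca_kd,
        ca_hill=ca_hill,
        ca_qfac=ca_qfac,
        bk_vhalf=bk_vhalf,
        bk_slope=bk_slope,
        bk_shift=bk_shift,
        bk_lg_caref=bk_lg_caref,
        erev=erev,
        is_ca=is_ca,
        n_gates=ng,
        n_channels=len(channels.channels),
    )


# Squid-type nodal Hodgkin-Huxley kinetics (classical rate functions).

def _hh_rates(v: float):
    def vtrap(x, y):
        if abs(x / y) < 1e-6:
            return y * (1.0 - x / y / 2.0)
        return x / (math.exp(x / y) - 1.0)

    am = 0.1 * vtrap(-(v + 40.0), 10.0)
    bm = 4.0 * math.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * math.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    an = 0.01 * vtrap(-(v + 55.0), 10.0)
    bn = 0.125 * math.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


def hh_steady_tau(v: float, q10_factor: float = 1.0):
    """Steady states and time constants (m, h, n) of the nodal HH mechanism."""
    am, bm, ah, bh, an, bn = _hh_rates(v)
    out = []
    for a, b in ((am, bm), (ah, bh), (an, bn)):
        a *= q10_factor
        b *= q10_factor
        out.append((a / (a + b), 1.0 / (a + b)))
    (mi, tm), (hi, th), (ni, tn) = out
    return (mi, hi, ni), (tm, th, tn)


def pack_node_hh(dt: float, v_min: float = -150.0, v_max: float = 80.0, dv: float = 0.05,
                 q10_factor: float = 1.0):
    """Tabulated (inf, qfac) for the three nodal HH gates at time step ``dt``."""
    nv = int(round((v_max - v_min) / dv)) + 1
    v = v_min + dv * np.arange(nv)
    inf = np.zeros((3, nv))
    qfac = np.zeros((3, nv))
    for i, vv in enumerate(v):
        (mi, hi, ni), (tm, th, tn) = hh_steady_tau(float(vv), q10_factor)
        inf[:, i] = (mi, hi, ni)
        qfac[:, i] = 1.0 - np.exp(-dt / np.array([tm, th, tn]))
    return inf, qfac
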