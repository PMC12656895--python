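"""Independent closed-form oracles used by the test suite.

These never call the package's integrator: the cable solution is the
classical steady-state input resistance of a chain of finite cylinders
(cascade of hyperbolic input-impedance recursions), evaluated directly from
the morphology and passive constants.
"""

from __future__ import annotations

import math


def _cylinder_constants(diam_um: float, g_leak: float, ra_ohm_cm: float):
    """(lambda_cm, r_inf_ohm) of a uniform passive cylinder."""
    d_cm = diam_um * 1e-4
    rm = 1.0 / g_leak  # Ohm cm^2
    lam = math.sqrt(rm * d_cm / (4.0 * ra_ohm_cm))
    r_axial_per_cm = 4.0 * ra_ohm_cm / (math.pi * d_cm**2)
    return lam, r_axial_per_cm * lam


def _cable_input_resistance(length_um, diam_um, g_leak, ra, r_load):
    """Input resistance of a finite cable terminated by r_load (Ohm;
    math.inf for a sealed end)."""
    lam, r_inf = _cylinder_constants(diam_um, g_leak, ra)
    l_el = (length_um * 1e-4) / lam
    t = math.tanh(l_el)
    if math.isinf(r_load):
        return r_inf / t
    return r_inf * (r_load + r_inf * t) / (r_inf + r_load * t)


def analytic_input_resistance_mohm(morphology, g_leak_per_kind, ra_ohm_cm=150.0):
    """Sealed-end DC input resistance at the soma of the standard chain.

    The soma is treated as a lumped membrane patch (its electrotonic length
    is negligible); the dendrite is a sealed-end cable; the axon side is the
    hillock cascaded into the alternating node/internode chain, sealed at
    the distal node.  Sections with zero leak are treated as lossless axial
    resistances (at DC an unloaded lossless section draws no current).
    """
    secs = {s.name: s for s in morphology.sections}
    soma = secs["soma"]
    dend = secs["dendrite"]

    # axon side, distal to proximal
    axon_sections = [s for s in morphology.sections if s.kind in ("node", "internode")]
    r_load = math.inf
    for s in reversed(axon_sections):
        g = g_leak_per_kind[s.kind]
        if g <= 0:
            # lossless: pure series axial resistance
            d_cm = s.diam_um * 1e-4
            r_series = 4.0 * ra_ohm_cm * (s.length_um * 1e-4) / (math.pi * d_cm**2)
            r_load = math.inf if math.isinf(r_load) else r_load + r_series
        else:
            r_load = _cable_input_resistance(s.length_um, s.diam_um, g, ra_ohm_cm, r_load)
    hill = secs["hillock"]
    r_axon = _cable_input_resistance(
        hill.length_um, hill.diam_um, g_leak_per_kind["hillock"], ra_ohm_cm, r_load
    )

    r_dend = _cable_input_resistance(
        dend.length_um, dend.diam_um, g_leak_per_kind["dendrite"], ra_ohm_cm, math.inf
    )

    area_soma_cm2 = math.pi * soma.diam_um * soma.length_um * 1e-8
    r_soma = 1.0 / (g_leak_per_kind["soma"] * area_soma_cm2)

    g_total = 1.0 / r_dend + 1.0 / r_axon + 1.0 / r_soma
    return 1.0 / g_total / 1e6


def brute_force_mann_whitney(x, y):
    """U statistics by direct pairwise comparison (0.5 per tie)."""
    u1 = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u1 += 1.0
            elif xi == yj:
                u1 += 0.5
    u2 = len(x) * len(y) - u1
    return u1, u2


def permutation_mann_whitney_p(x, y):
    """Exact two-sided p by enumerating all group assignments."""
    from itertools import combinations

    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    u_obs, _ = brute_force_mann_whitney(x, y)
    dev = abs(u_obs - mu)
    total = 0
    extreme = 0
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        grp = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in grp]
        u, _ = brute_force_mann_whitney(xs, ys)
        total += 1
        if abs(u - mu) >= dev - 1e-9:
            extreme += 1
    return extreme / total
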