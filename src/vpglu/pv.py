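"""Parvalbumin titration across calibrated populations and its statistics.

Every member of a population is re-simulated through the full protocol
battery at each total PV concentration (0 is the stored baseline;
1, 2, 5, 10 mM are the standard titration levels), with the buffer
equilibrated to baseline calcium at stimulus onset.  Population summaries
are arithmetic means and sample SDs per metric plus the pointwise mean F-I
curve; populations are compared with the Mann-Whitney U test (midrank ties,
exact null for small samples, tie-corrected normal approximation
otherwise).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .cable import SimulationDiverged
from .mcmc import ModelPopulation
from .protocols import MetricBundle, classify_phenotype, measure_metrics

__all__ = [
    "PV_CONCENTRATIONS_MM",
    "TitrationResult",
    "MannWhitneyResult",
    "titrate_pv",
    "population_summary",
    "mann_whitney_u",
    "compare_titration",
]

logger = logging.getLogger(__name__)

#: Standard titration levels (total PV, mM); 0 is always included as baseline.
PV_CONCENTRATIONS_MM = (1.0, 2.0, 5.0, 10.0)

#: Summary metrics reported per concentration.
SUMMARY_METRICS = (
    "peak_firing_current_pA",
    "peak_firing_rate_hz",
    "ramp_threshold_pA",
    "rheobase_pA",
    "input_resistance_MOhm",
)


def population_summary(bundles: list[MetricBundle]) -> dict:
    """Means, sample SDs, and the pointwise mean F-I curve of a population.

    ``None``-valued metrics (no-spike sentinels) are excluded per metric;
    a singleton population reports SD = 0.
    """
    if not bundles:
        raise ValueError("population summary needs at least one member")
    out: dict = {"n": len(bundles)}
    for name in SUMMARY_METRICS:
        vals = np.array(
            [getattr(b, name) for b in bundles if getattr(b, name) is not None],
            dtype=float,
        )
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            out[name] = {"mean": math.nan, "sd": math.nan, "n": 0}
        else:
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            out[name] = {"mean": float(vals.mean()), "sd": sd, "n": len(vals)}
    fi = np.array([b.fi_hz for b in bundles])
    out["fi_mean_hz"] = fi.mean(axis=0)
    out["fi_sd_hz"] = fi.std(axis=0, ddof=1) if len(bundles) > 1 else np.zeros(fi.shape[1])
    out["fi_grid_pA"] = bundles[0].fi_grid_pA.copy()
    out["db_fraction"] = float(
        np.mean([b.phenotype == "DB" for b in bundles])
    )
    out["mean_curve_phenotype"] = classify_phenotype(out["fi_mean_hz"])
    return out


@dataclass
class TitrationResult:
    """Per-concentration metric bundles and summaries for one population."""

    phenotype: str
    concentrations_mM: tuple[float, ...]
    bundles: dict[float, list[MetricBundle]]  # conc -> per-member metrics
    failed: dict[float, list[int]]  # conc -> member indices that diverged
    summaries: dict[float, dict] = field(default_factory=dict)

    def summary(self, conc: float) -> dict:
        if conc not in self.summaries:
            self.summaries[conc] = population_summary(self.bundles[conc])
        return self.summaries[conc]

    def metric_samples(self, conc: float, name: str) -> np.ndarray:
        vals = [getattr(b, name) for b in self.bundles[conc]]
        return np.array([v for v in vals if v is not None and np.isfinite(v)])


def titrate_pv(
    population: ModelPopulation,
    concentrations_mM=PV_CONCENTRATIONS_MM,
    cell_config=None,
    include_baseline: bool = True,
) -> TitrationResult:
    """Re-simulate every population member at each PV concentration.

    Concentration 0 reuses the population's stored baseline metrics (which
    re-simulation reproduces bit-identically, the integrator being
    deterministic).  Members that diverge at some concentration are flagged
    and excluded from that concentration's summary.
    """
    if len(population) == 0:
        raise ValueError("cannot titrate an empty population")
    from .config import desk_config

    cfg = cell_config or desk_config()
    concs = list(dict.fromkeys(
        ([0.0] if include_baseline else []) + [float(c) for c in concentrations_mM]
    ))
    bundles: dict[float, list[MetricBundle]] = {}
    failed: dict[float, list[int]] = {}
    grid = population.metrics[0].fi_grid_pA if population.metrics else None
    for conc in concs:
        if conc == 0.0 and population.metrics:
            bundles[0.0] = list(population.metrics)
            failed[0.0] = []
            continue
        row: list[MetricBundle] = []
        bad: list[int] = []
        for i in range(len(population)):
            cell = cfg.build(population.theta(i), pv_total_mM=conc)
            try:
                row.append(measure_metrics(cell, cfg.settings, grid))
            except SimulationDiverged:
                bad.append(i)
                logger.warning("member %d diverged at PV %.1f mM; excluded", i, conc)
        bundles[conc] = row
        failed[conc] = bad
    return TitrationResult(
        phenotype=population.phenotype,
        concentrations_mM=tuple(concs),
        bundles=bundles,
        failed=failed,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U

@dataclass(frozen=True)
class MannWhitneyResult:
    """Both one-sided statistics, the conventional min(U1, U2), and the
    two-sided p-value (exact for small samples, normal approximation with
    tie correction otherwise)."""

    u1: float
    u2: float
    u: float
    p_value: float
    method: str


#: Total sample size at or below which the exact null distribution is used.
EXACT_LIMIT = 20


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    i = 0
    sorted_vals = pooled[order]
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _exact_two_sided_p(ranks2: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact permutation null of U over all choices of n1 ranks (doubled
    midranks keep the dynamic program integral)."""
    r2 = np.round(2 * ranks2).astype(int)
    total = int(r2.sum())
    n = len(r2)
    # f[k][s]: number of k-subsets of the first items with doubled-rank sum s
    f = [dict() for _ in range(n1 + 1)]
    f[0][0] = 1
    for r in r2:
        for k in range(min(n1, n) - 1, -1, -1):
            if not f[k]:
                continue
            tgt = f[k + 1]
            for s, c in f[k].items():
                tgt[s + r] = tgt.get(s + r, 0) + c
    dist = f[n1]  # doubled rank-sum of sample 1 -> count
    n2 = n - n1
    mu = n1 * n2 / 2.0
    # doubled U1 = doubled R1 - n1(n1+1)
    eps = 1e-9
    obs_dev = abs(u_obs - mu)
    extreme = 0
    count_total = 0
    for s2, c in dist.items():
        u1 = s2 / 2.0 - n1 * (n1 + 1) / 2.0
        count_total += c
        if abs(u1 - mu) >= obs_dev - eps:
            extreme += c
    return extreme / count_total


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    ``u`` is the smaller of the two one-sided statistics.  The p-value is
    exact (permutation null over the observed midranks) when
    ``n1 + n2 <= 20`` and otherwise a normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    if n1 + n2 <= EXACT_LIMIT:
        p = _exact_two_sided_p(ranks, n1, u1)
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum()
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
            z = max(z, 0.0)
            p = math.erfc(z / math.sqrt(2.0))
        method = "normal"
    return MannWhitneyResult(u1=float(u1), u2=float(u2), u=float(u),
                             p_value=float(min(p, 1.0)), method=method)


def compare_titration(result: TitrationResult, metrics=SUMMARY_METRICS) -> list[dict]:
    """Baseline-vs-concentration Mann-Whitney comparisons per metric.

    Mirrors the figure-style presentation: unpaired tests of the 0 mM
    population against each PV level, uncorrected for multiple comparisons.
    """
    rows = []
    base = 0.0
    for conc in result.concentrations_mM:
        if conc == base:
            continue
        for name in metrics:
            xs = result.metric_samples(base, name)
            ys = result.metric_samples(conc, name)
            if len(xs) == 0 or len(ys) == 0:
                continue
            r = mann_whitney_u(xs, ys)
            rows.append({
                "phenotype": result.phenotype,
                "metric": name,
                "baseline_mM": base,
                "pv_mM": conc,
                "mean_baseline": float(xs.mean()),
                "mean_pv": float(ys.mean()),
                "u1": r.u1, "u2": r.u2, "u": r.u,
                "p_value": r.p_value, "method": r.method,
            })
    return rows
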