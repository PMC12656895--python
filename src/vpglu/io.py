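"""Result persistence: delimited-text tables, trace containers, manifests.

Populations and titration results are written as tab-separated tables whose
header rows carry units; voltage traces go to TSV for single runs and to a
compressed array container (``.npz``) for batches.  Every CLI invocation
writes a JSON run manifest (command, config hash, seed, package version,
timestamps, output paths) so any deterministic artifact can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .cable import VoltageTrace
from .channels import PARAM_NAMES
from .mcmc import ModelPopulation
from .protocols import MetricBundle
from .pv import TitrationResult

__all__ = [
    "write_population",
    "read_population",
    "write_titration",
    "write_trace",
    "read_trace",
    "write_trace_batch",
    "write_manifest",
]

logger = logging.getLogger(__name__)

_METRIC_COLUMNS = [
    ("input_resistance_MOhm", "MOhm"),
    ("ramp_threshold_pA", "pA"),
    ("peak_firing_current_pA", "pA"),
    ("peak_firing_rate_hz", "Hz"),
    ("rheobase_pA", "pA"),
    ("ahp_mV", "mV"),
    ("rmp_mV", "mV"),
]


def _population_frame(pop: ModelPopulation) -> pd.DataFrame:
    rows = []
    for i, m in enumerate(pop.metrics):
        row = {f"{n}_S_per_cm2": pop.thetas[i, j] for j, n in enumerate(PARAM_NAMES)}
        for name, _unit in _METRIC_COLUMNS:
            v = getattr(m, name)
            row[name] = np.nan if v is None else v
        for amp, rate in zip(m.fi_grid_pA, m.fi_hz):
            row[f"fi_{amp:g}pA_hz"] = rate
        row["phenotype"] = m.phenotype
        row["score"] = pop.scores[i]
        rows.append(row)
    if not rows:
        cols = [f"{n}_S_per_cm2" for n in PARAM_NAMES]
        cols += [n for n, _ in _METRIC_COLUMNS] + ["phenotype", "score"]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def write_population(pop: ModelPopulation, path) -> Path:
    """One row per accepted model: theta (9 columns), metrics, phenotype, score."""
    path = Path(path)
    df = _population_frame(pop)
    if df.empty:
        logger.warning("writing empty %s population to %s", pop.phenotype, path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# phenotype={pop.phenotype} n={len(pop)}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    return path


def read_population(path) -> ModelPopulation:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    phenotype = "NDB"
    for tok in header.lstrip("# ").split():
        if tok.startswith("phenotype="):
            phenotype = tok.split("=", 1)[1]
    if df.empty:
        return ModelPopulation(np.empty((0, 9)), [], np.empty(0), phenotype)
    thetas = df[[f"{n}_S_per_cm2" for n in PARAM_NAMES]].to_numpy()
    fi_cols = [c for c in df.columns if c.startswith("fi_") and c.endswith("pA_hz")]
    grid = np.array([float(c[3:-5]) for c in fi_cols])
    order = np.argsort(grid)
    grid = grid[order]
    fi_cols = [fi_cols[i] for i in order]
    metrics = []
    for _, row in df.iterrows():
        def opt(v):
            return None if pd.isna(v) else float(v)

        metrics.append(MetricBundle(
            input_resistance_MOhm=float(row["input_resistance_MOhm"]),
            fi_hz=row[fi_cols].to_numpy(dtype=float),
            fi_grid_pA=grid.copy(),
            ramp_threshold_pA=opt(row["ramp_threshold_pA"]),
            peak_firing_current_pA=opt(row["peak_firing_current_pA"]),
            peak_firing_rate_hz=float(row["peak_firing_rate_hz"]),
            rheobase_pA=opt(row["rheobase_pA"]),
            ahp_mV=opt(row["ahp_mV"]),
            rmp_mV=opt(row["rmp_mV"]),
            phenotype=str(row["phenotype"]),
        ))
    return ModelPopulation(
        thetas=thetas,
        metrics=metrics,
        scores=df["score"].to_numpy(dtype=float),
        phenotype=phenotype,
    )


def write_titration(result: TitrationResult, out_dir) -> dict[str, Path]:
    """Per-(model, concentration) metric table plus per-concentration summary
    and figure-ready mean F-I curves, all tab-separated."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for conc in result.concentrations_mM:
        for i, m in enumerate(result.bundles[conc]):
            row = {"pv_mM": conc, "member": i}
            for name, _unit in _METRIC_COLUMNS:
                v = getattr(m, name)
                row[name] = np.nan if v is None else v
            row["phenotype"] = m.phenotype
            rows.append(row)
    per_model = out_dir / f"titration_{result.phenotype}_models.tsv"
    pd.DataFrame(rows).to_csv(per_model, sep="\t", index=False)

    srows, firows = [], []
    for conc in result.concentrations_mM:
        s = result.summary(conc)
        row = {"pv_mM": conc, "n": s["n"], "db_fraction": s["db_fraction"],
               "mean_curve_phenotype": s["mean_curve_phenotype"]}
        for name, _unit in _METRIC_COLUMNS:
            if name in s:
                row[f"{name}_mean"] = s[name]["mean"]
                row[f"{name}_sd"] = s[name]["sd"]
        srows.append(row)
        for amp, mean, sd in zip(s["fi_grid_pA"], s["fi_mean_hz"], s["fi_sd_hz"]):
            firows.append({"pv_mM": conc, "amp_pA": amp,
                           "rate_mean_hz": mean, "rate_sd_hz": sd})
    summary = out_dir / f"titration_{result.phenotype}_summary.tsv"
    pd.DataFrame(srows).to_csv(summary, sep="\t", index=False)
    fi = out_dir / f"titration_{result.phenotype}_fi.tsv"
    pd.DataFrame(firows).to_csv(fi, sep="\t", index=False)
    return {"models": per_model, "summary": summary, "fi": fi}


def write_trace(trace: VoltageTrace, path) -> Path:
    """Tabular text trace: time (ms), somatic V (mV), injected I (pA)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# dt_ms={trace.dt_ms!r} equilibration_ms={trace.equilibration_ms!r}\n")
        trace.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.17g")
    return path


def read_trace(path) -> VoltageTrace:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(tok.split("=", 1) for tok in header)
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    return VoltageTrace(
        t=df["time_ms"].to_numpy(),
        v=df["v_mV"].to_numpy(),
        i=df["i_pA"].to_numpy(),
        dt_ms=float(meta["dt_ms"]),
        equilibration_ms=float(meta["equilibration_ms"]),
    )


def write_trace_batch(traces: dict[str, VoltageTrace], path) -> Path:
    """Binary array container for batch runs (one npz; dt stored per trace)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for key, tr in traces.items():
        arrays[f"{key}/t_ms"] = tr.t
        arrays[f"{key}/v_mV"] = tr.v
        arrays[f"{key}/i_pA"] = tr.i
        arrays[f"{key}/meta"] = np.array([tr.dt_ms, tr.equilibration_ms])
    np.savez_compressed(path, **arrays)
    return path


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir, command: str, config_obj, seed: int | None,
                   outputs: list, extra: dict | None = None) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config_hash": config_hash(config_obj),
        "config": config_obj,
        "seed": seed,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": [str(p) for p in outputs],
    }
    if extra:
        manifest.update(extra)
    path = out_dir / f"manifest_{command}_{manifest['config_hash']}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
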