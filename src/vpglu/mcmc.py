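"""Affine-invariant ensemble MCMC over 9-dimensional conductance space.

The sampler is the stretch move: walker ``X_i`` proposes
``Y = X_j + z (X_i - X_j)`` with a partner ``X_j`` drawn from the
complementary half-ensemble and ``z`` drawn with density proportional to
``1/sqrt(z)`` on ``[1/a, a]`` (``a = 2``), accepted with probability
``min(1, z^{d-1} exp(logp(Y) - logp(X_i)))``.

The log-probability is a Boltzmann form on the calibration score,
``logp = -score/T`` inside the uniform prior box and ``-inf`` outside.  A
parameter set's score is the mean normalized distance between its simulated
validation metrics and the target bundle (input resistance, ramp threshold,
peak firing current, and the summed F-I error).

A calibration is ``n_runs`` independent restarts of ``n_walkers`` walkers
iterated ``n_iterations`` times; restart ``r`` initializes walkers at the
prior-box center plus Gaussian noise whose scale grows linearly with ``r``
(progressively wider exploration), clipped into the prior box.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .cable import SimulationDiverged
from .channels import ConductanceVector
from .protocols import MetricBundle, measure_metrics
from .targets import SCORED_METRICS, TargetBundle

__all__ = [
    "PriorSpec",
    "CalibrationConfig",
    "CalibrationHistory",
    "ModelPopulation",
    "ScoreEvaluator",
    "default_prior",
    "score_parameter_set",
    "log_probability",
    "sample_stretch_z",
    "stretch_update",
    "run_calibration",
    "assemble_population",
    "SCALE_PRESETS",
]

logger = logging.getLogger(__name__)

#: Finite stand-in for an infinite score inside the sampler (see run_calibration).
INFEASIBLE_SCORE_CAP = 1e6


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors: per-parameter [lower, upper) box."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != hi.shape:
            raise ValueError("prior bounds must have matching shapes")
        if np.any(lo < 0):
            raise ValueError("conductance priors must be >= 0")
        if np.any(lo >= hi):
            raise ValueError("prior lower bounds must be < upper bounds")

    @property
    def dim(self) -> int:
        return len(self.lower)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def contains(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))

    def clip(self, theta: np.ndarray) -> np.ndarray:
        return np.clip(theta, self.lower, self.upper)


def default_prior() -> PriorSpec:
    """Physiological box: active conductances in [0, 1] S/cm2, leak in [0, 1e-3]."""
    upper = np.ones(9)
    upper[8] = 1e-3
    return PriorSpec(lower=np.zeros(9), upper=upper)


@dataclass(frozen=True)
class CalibrationConfig:
    """Ensemble-MCMC run plan.

    ``noise_scale`` sets the restart initialization: run ``r`` (1-based)
    draws walkers from N(center, (noise_scale * r * box_width)^2), clipped
    into the prior box — a nondecreasing noise schedule.
    """

    n_runs: int = 10
    n_walkers: int = 400
    n_iterations: int = 25
    noise_scale: float = 0.05
    threshold: float = 0.5
    temperature: float = 0.05
    stretch_a: float = 2.0

    def __post_init__(self):
        if min(self.n_runs, self.n_walkers, self.n_iterations) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_walkers % 2 != 0:
            raise ValueError("n_walkers must be even (half-ensemble updates)")
        if self.temperature <= 0 or self.stretch_a <= 1:
            raise ValueError("invalid temperature or stretch parameter")

    def noise_sd(self, run_index: int, prior: PriorSpec,
                 base: np.ndarray | None = None) -> np.ndarray:
        """Initialization noise SD for 1-based restart ``run_index``.

        Conductances span decades, so the noise is scaled per dimension to
        the base guess (with a small floor of 1% of the box width): restart
        r draws from N(base, (noise_scale * r * scale)^2).  Box-width
        scaling would put multi-millisiemens perturbations on channels whose
        viable densities are a thousandfold smaller, leaving essentially
        every walker electrically dead.
        """
        if base is None:
            ref = prior.width
        else:
            ref = np.maximum(np.abs(np.asarray(base, dtype=float)),
                             0.01 * prior.width)
        return self.noise_scale * run_index * ref


#: Named run-plan presets: quick smoke checks, single-workstation sweeps,
#: and the full configuration (400 walkers x 25 iterations x 10 restarts).
SCALE_PRESETS = {
    "smoke": CalibrationConfig(n_runs=1, n_walkers=8, n_iterations=5),
    "desk": CalibrationConfig(n_runs=3, n_walkers=64, n_iterations=15),
    "full": CalibrationConfig(n_runs=10, n_walkers=400, n_iterations=25),
}


def score_parameter_set(m: MetricBundle | None, target: TargetBundle) -> float:
    """Mean normalized distance between a model's metrics and the target.

    Four terms, equally weighted: |input resistance - mean|/norm,
    |ramp threshold - mean|/norm, |peak firing current - mean|/norm, and
    the F-I term sum_k |fi_model(k) - fi_target(k)| / fi_normalizer.
    Incomplete metrics (nonspiking, no ramp spike, failed simulation) score
    +inf.  Lower is better; exact agreement scores 0.
    """
    if m is None or not m.is_complete():
        return math.inf
    if len(m.fi_hz) != len(target.fi_mean_hz):
        raise ValueError("model and target F-I grids differ")
    values = {
        "input_resistance": m.input_resistance_MOhm,
        "ramp_threshold": m.ramp_threshold_pA,
        "peak_firing_current": m.peak_firing_current_pA,
    }
    terms = [
        abs(values[k] - target.stats[k].mean) / target.stats[k].norm
        for k in SCORED_METRICS
    ]
    terms.append(float(np.abs(m.fi_hz - target.fi_mean_hz).sum()) / target.fi_norm)
    return float(np.mean(terms))


class ScoreEvaluator:
    """Scores parameter vectors against a target bundle, with memoization.

    The simulation is deterministic, so a score depends only on theta; the
    cache avoids re-simulating walkers whose proposals were rejected.
    """

    def __init__(self, target: TargetBundle, cell_config=None):
        from .config import desk_config

        self.target = target
        self.cell_config = cell_config or desk_config()
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def metrics(self, theta: np.ndarray, fail_fast: bool = False) -> MetricBundle | None:
        try:
            cell = self.cell_config.build(ConductanceVector.from_array(theta))
            return measure_metrics(
                cell, self.cell_config.settings, self.target.fi_grid_pA,
                fail_fast=fail_fast,
            )
        except SimulationDiverged:
            return None

    def score(self, theta: np.ndarray) -> float:
        key = np.asarray(theta, dtype=float).tobytes()
        if key not in self._cache:
            self.n_evaluations += 1
            self._cache[key] = score_parameter_set(
                self.metrics(theta, fail_fast=True), self.target
            )
        return self._cache[key]



def log_probability(
    theta: np.ndarray,
    target: TargetBundle | None = None,
    prior: PriorSpec | None = None,
    temperature: float = 0.05,
    evaluator: ScoreEvaluator | None = None,
) -> float:
    """Boltzmann log-probability: -score/T inside the prior box, else -inf."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    prior = prior or default_prior()
    theta = np.asarray(theta, dtype=float)
    if not prior.contains(theta):
        return -math.inf
    if evaluator is None:
        evaluator = ScoreEvaluator(target)
    s = evaluator.score(theta)
    return -s / temperature


def sample_stretch_z(rng: np.random.Generator, a: float = 2.0, size=None):
    """Draw z with density proportional to 1/sqrt(z) on [1/a, a]."""
    u = rng.random(size)
    s = math.sqrt(a)
    return ((s - 1.0 / s) * u + 1.0 / s) ** 2


def stretch_update(
    positions: np.ndarray,
    logps: np.ndarray,
    logp_fn: Callable[[np.ndarray], float],
    rng: np.random.Generator,
    a: float = 2.0,
):
    """One stretch-move sweep over the ensemble (two half-ensemble passes).

    Returns ``(positions, logps, acceptance_fraction)``; inputs are not
    modified.
    """
    pos = np.array(positions, dtype=float)
    lp = np.array(logps, dtype=float)
    k, d = pos.shape
    if k < 4:
        raise ValueError("need at least 4 walkers for half-ensemble updates")
    half = k // 2
    accepted = 0
    for first, second in ((slice(0, half), slice(half, k)), (slice(half, k), slice(0, half))):
        active = np.arange(k)[first]
        other = pos[second]
        partners = rng.integers(0, len(other), size=len(active))
        z = sample_stretch_z(rng, a, size=len(active))
        for idx, j, zz in zip(active, partners, z):
            y = other[j] + zz * (pos[idx] - other[j])
            lp_new = logp_fn(y)
            log_ratio = (d - 1) * math.log(zz) + lp_new - lp[idx]
            if math.log(rng.random()) < log_ratio:
                pos[idx] = y
                lp[idx] = lp_new
                accepted += 1
    return pos, lp, accepted / k


@dataclass
class CalibrationHistory:
    """Full record of a calibration: every walker position and score."""

    positions: np.ndarray  # (n_runs, n_iterations, n_walkers, dim)
    scores: np.ndarray  # (n_runs, n_iterations, n_walkers)
    acceptance: np.ndarray  # (n_runs, n_iterations)
    config: CalibrationConfig
    seed: int
    phenotype: str

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """All recorded (theta, score) pairs as flat arrays."""
        d = self.positions.shape[-1]
        return self.positions.reshape(-1, d), self.scores.reshape(-1)

    @property
    def best_score(self) -> float:
        return float(np.nanmin(self.scores))


def run_calibration(
    target: TargetBundle,
    config: CalibrationConfig | None = None,
    seed: int = 0,
    cell_config=None,
    prior: PriorSpec | None = None,
    base_guess: np.ndarray | None = None,
    evaluator: ScoreEvaluator | None = None,
) -> CalibrationHistory:
    """Run the full restart schedule against one target bundle.

    Deterministic for a given seed: restart ``r`` uses an RNG derived from
    ``(seed, r)``.  Raises if every walker of a restart is infeasible
    (score = +inf at initialization with zero ensemble spread).
    """
    config = config or CalibrationConfig()
    prior = prior or default_prior()
    if evaluator is None:
        evaluator = ScoreEvaluator(target, cell_config)
    if base_guess is None:
        from .config import CALIBRATION_BASE_GUESS

        base_guess = CALIBRATION_BASE_GUESS.get(
            target.phenotype, prior.center
        )
    base = np.asarray(base_guess, dtype=float)
    t = config.temperature

    # Inside the prior box an infeasible (nonspiking/diverged) parameter set
    # is given a large finite penalty instead of -inf so that an ensemble
    # initialized in dead territory can still diffuse toward the feasible
    # region; the posterior mass it carries is numerically zero either way.
    def logp(th: np.ndarray) -> float:
        if not prior.contains(th):
            return -math.inf
        return -min(evaluator.score(th), INFEASIBLE_SCORE_CAP) / t

    d = prior.dim
    k = config.n_walkers
    positions = np.empty((config.n_runs, config.n_iterations, k, d))
    scores = np.empty((config.n_runs, config.n_iterations, k))
    acceptance = np.empty((config.n_runs, config.n_iterations))

    for r in range(1, config.n_runs + 1):
        rng = np.random.default_rng([seed, r])
        sd = config.noise_sd(r, prior, base)
        pos = prior.clip(base + sd * rng.standard_normal((k, d)))
        lp = np.array([logp(th) for th in pos])
        if np.all(np.isinf(lp)) and np.allclose(pos, pos[0]):
            raise RuntimeError(
                "calibration setup error: every walker infeasible at an "
                "initialization with no ensemble spread; widen the noise "
                "schedule or move the base guess"
            )
        for it in range(config.n_iterations):
            pos, lp, acc = stretch_update(pos, lp, logp, rng, config.stretch_a)
            positions[r - 1, it] = pos
            scores[r - 1, it] = -lp * t
            acceptance[r - 1, it] = acc
        logger.info(
            "restart %d/%d: best score %.3f, final acceptance %.2f",
            r, config.n_runs, float(np.nanmin(scores[r - 1])), acc,
        )
    return CalibrationHistory(
        positions=positions,
        scores=scores,
        acceptance=acceptance,
        config=config,
        seed=seed,
        phenotype=target.phenotype,
    )


@dataclass
class ModelPopulation:
    """Accepted parameter sets with their re-simulated metrics."""

    thetas: np.ndarray  # (n, 9)
    metrics: list[MetricBundle]
    scores: np.ndarray  # (n,)
    phenotype: str

    def __len__(self) -> int:
        return len(self.scores)

    def theta(self, i: int) -> ConductanceVector:
        return ConductanceVector.from_array(self.thetas[i])


def _deduplicate(thetas: np.ndarray, scores: np.ndarray, rtol: float = 1e-9):
    """Keep one representative of each near-identical parameter vector."""
    order = np.argsort(scores, kind="stable")
    kept: list[int] = []
    for i in order:
        th = thetas[i]
        dup = False
        for j in kept:
            ref = thetas[j]
            if np.all(np.abs(th - ref) <= rtol * np.maximum(np.abs(ref), 1e-30)):
                dup = True
                break
        if not dup:
            kept.append(i)
    kept_arr = np.array(kept, dtype=int)
    return thetas[kept_arr], scores[kept_arr]


def assemble_population(
    history: CalibrationHistory,
    target: TargetBundle,
    threshold: float | None = None,
    cell_config=None,
    evaluator: ScoreEvaluator | None = None,
    max_members: int | None = None,
) -> ModelPopulation:
    """Select, deduplicate, and re-validate the accepted parameter sets.

    Candidates with recorded score <= threshold are deduplicated (relative
    tolerance 1e-9), re-simulated from scratch, and kept only when the
    recomputed score stays within threshold and the re-simulated F-I curve
    classifies to the target phenotype.  An empty result is a warning, not
    an error.
    """
    if threshold is None:
        threshold = history.config.threshold
    from .config import desk_config

    cfg = cell_config or desk_config()
    thetas, scores = history.flat()
    sel = np.isfinite(scores) & (scores <= threshold)
    thetas, scores = _deduplicate(thetas[sel], scores[sel])
    if max_members is not None:
        thetas, scores = thetas[:max_members], scores[:max_members]
    ev = evaluator or ScoreEvaluator(target, cfg)
    kept_t, kept_m, kept_s = [], [], []
    for th in thetas:
        m = ev.metrics(th)
        s = score_parameter_set(m, target)
        if s <= threshold and m is not None and m.phenotype == target.phenotype:
            kept_t.append(th)
            kept_m.append(m)
            kept_s.append(s)
    if not kept_t:
        warnings.warn(
            f"empty {target.phenotype} population at threshold {threshold}",
            stacklevel=2,
        )
        return ModelPopulation(
            thetas=np.empty((0, prior_dim := thetas.shape[1] if thetas.size else 9)),
            metrics=[],
            scores=np.empty(0),
            phenotype=target.phenotype,
        )
    return ModelPopulation(
        thetas=np.array(kept_t),
        metrics=kept_m,
        scores=np.array(kept_s),
        phenotype=target.phenotype,
    )
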