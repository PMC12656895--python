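"""Scoring, the stretch-move sampler, and population assembly."""

import dataclasses
import math

import numpy as np
import pytest

from vpglu.mcmc import (
    CalibrationConfig,
    CalibrationHistory,
    PriorSpec,
    SCALE_PRESETS,
    ScoreEvaluator,
    assemble_population,
    default_prior,
    log_probability,
    run_calibration,
    sample_stretch_z,
    score_parameter_set,
    stretch_update,
)
from vpglu.protocols import MetricBundle
from vpglu.targets import builtin_targets


def bundle_matching(target, phenotype=None) -> MetricBundle:
    """A metric bundle that reproduces the target exactly (score 0)."""
    return MetricBundle(
        input_resistance_MOhm=target.stats["input_resistance"].mean,
        fi_hz=target.fi_mean_hz.copy(),
        fi_grid_pA=target.fi_grid_pA.copy(),
        ramp_threshold_pA=target.stats["ramp_threshold"].mean,
        peak_firing_current_pA=target.stats["peak_firing_current"].mean,
        peak_firing_rate_hz=float(target.fi_mean_hz.max()),
        rheobase_pA=target.stats["rheobase"].mean,
        ahp_mV=15.0,
        rmp_mV=-65.0,
        phenotype=phenotype or target.phenotype,
    )


class TestScore:
    def test_exact_match_scores_zero(self):
        t = builtin_targets("NDB")
        assert score_parameter_set(bundle_matching(t), t) == 0.0

    def test_single_metric_off_by_one_normalizer_scores_quarter(self):
        t = builtin_targets("NDB")
        m = bundle_matching(t)
        m = dataclasses.replace(
            m, ramp_threshold_pA=m.ramp_threshold_pA + t.stats["ramp_threshold"].norm
        )
        assert score_parameter_set(m, t) == pytest.approx(0.25)

    def test_score_is_monotone_in_each_metric(self):
        t = builtin_targets("DB")
        base = bundle_matching(t)
        s0 = score_parameter_set(base, t)
        for field, delta in [("input_resistance_MOhm", 100.0),
                             ("ramp_threshold_pA", 5.0),
                             ("peak_firing_current_pA", 10.0)]:
            worse = dataclasses.replace(base, **{field: getattr(base, field) + delta})
            even_worse = dataclasses.replace(base, **{field: getattr(base, field) + 2 * delta})
            assert score_parameter_set(worse, t) > s0
            assert score_parameter_set(even_worse, t) > score_parameter_set(worse, t)
        worse_fi = dataclasses.replace(base, fi_hz=base.fi_hz + 1.0)
        assert score_parameter_set(worse_fi, t) > s0

    def test_incomplete_metrics_score_infinite(self):
        t = builtin_targets("NDB")
        assert score_parameter_set(None, t) == math.inf
        m = dataclasses.replace(bundle_matching(t), ramp_threshold_pA=None)
        assert score_parameter_set(m, t) == math.inf


class _FakeEvaluator:
    """Quadratic score bowl: cheap stand-in for the simulation evaluator."""

    def __init__(self, center, phenotype="NDB"):
        self.center = np.asarray(center, dtype=float)
        self.target = builtin_targets(phenotype)

    def score(self, theta):
        return float(np.sum((np.asarray(theta) - self.center) ** 2)) * 50.0

    def metrics(self, theta):
        return bundle_matching(self.target)


class TestLogProbability:
    def test_out_of_prior_support_is_minus_infinity(self):
        prior = default_prior()
        ev = _FakeEvaluator(np.zeros(9))
        theta = np.zeros(9)
        theta[0] = -1e-6
        assert log_probability(theta, prior=prior, evaluator=ev) == -math.inf

    def test_zero_score_maximizes_log_probability(self):
        prior = default_prior()
        center = np.full(9, 0.1)
        center[8] = 1e-4
        ev = _FakeEvaluator(center)
        assert log_probability(center, prior=prior, evaluator=ev) == 0.0
        other = center + 1e-3
        assert log_probability(other, prior=prior, evaluator=ev) < 0.0

    def test_halving_temperature_doubles_log_probability_gap(self):
        prior = default_prior()
        ev = _FakeEvaluator(np.full(9, 0.1))
        a = np.full(9, 0.12)
        b = np.full(9, 0.2)
        a[8] = b[8] = 1e-4
        gap_t = (log_probability(a, prior=prior, evaluator=ev, temperature=0.1)
                 - log_probability(b, prior=prior, evaluator=ev, temperature=0.1))
        gap_half = (log_probability(a, prior=prior, evaluator=ev, temperature=0.05)
                    - log_probability(b, prior=prior, evaluator=ev, temperature=0.05))
        assert gap_half == pytest.approx(2 * gap_t, rel=1e-12)

    def test_invalid_temperature_rejected(self):
        with pytest.raises(ValueError):
            log_probability(np.zeros(9), temperature=0.0,
                            evaluator=_FakeEvaluator(np.zeros(9)))


class TestStretchMove:
    def test_z_draw_mean_matches_closed_form(self):
        # density ~ 1/sqrt(z) on [1/2, 2]:
        # E[z] = (2/3)(2^1.5 - 0.5^1.5) / (2 (2^0.5 - 0.5^0.5))
        rng = np.random.default_rng(42)
        z = sample_stretch_z(rng, a=2.0, size=1_000_000)
        expected = (2.0 / 3.0) * (2**1.5 - 0.5**1.5) / (2.0 * (2**0.5 - 0.5**0.5))
        assert z.min() >= 0.5 and z.max() <= 2.0
        assert z.mean() == pytest.approx(expected, rel=0.003)

    def _run_gaussian(self, logp, rng, n_iter=3000, n_walkers=32, dim=2, x0=None):
        pos = rng.standard_normal((n_walkers, dim)) * 0.1 + (x0 if x0 is not None else 0)
        lp = np.array([logp(x) for x in pos])
        chain = []
        acc = []
        for i in range(n_iter):
            pos, lp, a = stretch_update(pos, lp, logp, rng)
            acc.append(a)
            if i >= n_iter // 4:
                chain.append(pos.copy())
        return np.concatenate(chain), float(np.mean(acc))

    def test_recovers_standard_gaussian_moments(self):
        def logp(x):
            return -0.5 * float(np.dot(x, x))

        rng = np.random.default_rng(7)
        samples, _ = self._run_gaussian(logp, rng, n_iter=5000)
        assert np.abs(samples.mean(axis=0)).max() < 0.05
        cov = np.cov(samples.T)
        assert np.abs(cov - np.eye(2)).max() < 0.1

    def test_affine_invariance_of_acceptance_rate(self):
        # an affine reparametrization leaves the walker dynamics identical
        scale = np.array([5.0, 0.2])

        def logp_iso(x):
            return -0.5 * float(np.dot(x, x))

        def logp_aniso(x):
            y = x / scale
            return -0.5 * float(np.dot(y, y))

        _, acc_iso = self._run_gaussian(logp_iso, np.random.default_rng(11),
                                        n_iter=1500)
        _, acc_aniso = self._run_gaussian(logp_aniso, np.random.default_rng(11),
                                          n_iter=1500)
        assert acc_iso == pytest.approx(acc_aniso, abs=0.02)

    def test_agrees_with_independent_ensemble_sampler(self):
        # independent oracle: emcee's implementation of the same algorithm
        emcee = pytest.importorskip("emcee")

        def logp(x):
            return -0.5 * float(np.dot(x, x))

        rng = np.random.default_rng(3)
        ours, _ = self._run_gaussian(logp, rng, n_iter=4000)
        sampler = emcee.EnsembleSampler(32, 2, logp)
        state = sampler.run_mcmc(np.random.default_rng(4).standard_normal((32, 2)) * 0.1,
                                 4000, progress=False)
        theirs = sampler.get_chain(discard=1000, flat=True)
        assert np.abs(ours.std(axis=0) - theirs.std(axis=0)).max() < 0.05

    def test_two_point_target_occupancy_is_symmetric(self):
        # flat density on two disjoint unit-mass intervals
        def logp(x):
            v = x[0]
            if 0.0 <= v <= 0.2 or 1.0 <= v <= 1.2:
                return 0.0
            return -math.inf

        rng = np.random.default_rng(5)
        pos = np.concatenate([
            rng.uniform(0.0, 0.2, size=(8, 1)),
            rng.uniform(1.0, 1.2, size=(8, 1)),
        ])
        lp = np.array([logp(x) for x in pos])
        occupancy = []
        for _ in range(6000):
            pos, lp, _ = stretch_update(pos, lp, logp, rng)
            occupancy.append(np.mean(pos[:, 0] > 0.6))
        frac = float(np.mean(occupancy[1000:]))
        assert frac == pytest.approx(0.5, abs=0.02)


class TestRunCalibration:
    def test_identical_seeds_give_identical_histories(self):
        ev = _FakeEvaluator(np.full(9, 0.1))
        cfg = CalibrationConfig(n_runs=2, n_walkers=8, n_iterations=5)
        h1 = run_calibration(ev.target, cfg, seed=123, evaluator=ev)
        h2 = run_calibration(ev.target, cfg, seed=123, evaluator=ev)
        assert np.array_equal(h1.positions, h2.positions)
        assert np.array_equal(h1.scores, h2.scores)

    def test_history_shape_matches_plan(self):
        ev = _FakeEvaluator(np.full(9, 0.1))
        cfg = CalibrationConfig(n_runs=2, n_walkers=8, n_iterations=5)
        h = run_calibration(ev.target, cfg, seed=1, evaluator=ev)
        assert h.positions.shape == (2, 5, 8, 9)
        assert h.scores.shape == (2, 5, 8)

    def test_full_scale_defaults_match_published_plan(self):
        cfg = CalibrationConfig()
        assert (cfg.n_runs, cfg.n_iterations, cfg.n_walkers) == (10, 25, 400)
        full = SCALE_PRESETS["full"]
        assert (full.n_runs, full.n_iterations, full.n_walkers) == (10, 25, 400)

    def test_noise_schedule_is_nondecreasing(self):
        cfg = CalibrationConfig()
        prior = default_prior()
        sds = [cfg.noise_sd(r, prior) for r in range(1, 11)]
        for a, b in zip(sds, sds[1:]):
            assert np.all(b >= a)

    def test_walkers_stay_inside_prior_box(self):
        ev = _FakeEvaluator(np.full(9, 0.1))
        cfg = CalibrationConfig(n_runs=1, n_walkers=8, n_iterations=10)
        h = run_calibration(ev.target, cfg, seed=2, evaluator=ev)
        prior = default_prior()
        flat, scores = h.flat()
        ok = np.isfinite(scores)
        assert np.all(flat[ok] >= prior.lower - 1e-12)
        assert np.all(flat[ok] <= prior.upper + 1e-12)


class TestAssemblePopulation:
    def _history_with(self, thetas, scores, phenotype="NDB"):
        thetas = np.asarray(thetas, dtype=float)[None, None]
        scores = np.asarray(scores, dtype=float)[None, None]
        return CalibrationHistory(
            positions=thetas, scores=scores,
            acceptance=np.zeros((1, 1)),
            config=CalibrationConfig(n_runs=1, n_walkers=4, n_iterations=1),
            seed=0, phenotype=phenotype,
        )

    def test_bitwise_duplicate_walkers_collapse_to_one_member(self):
        theta = np.full(9, 0.1)
        ev = _FakeEvaluator(theta)
        h = self._history_with([theta, theta.copy(), theta * 1.5, theta * 2.0],
                               [0.0, 0.0, 0.3, 0.4])
        pop = assemble_population(h, ev.target, threshold=0.5, evaluator=ev)
        dup_count = sum(np.allclose(t, theta) for t in pop.thetas)
        assert dup_count == 1

    def test_zero_threshold_gives_near_empty_population(self):
        ev = _FakeEvaluator(np.full(9, 0.1))
        h = self._history_with([np.full(9, 0.2)] * 4, [0.1, 0.2, 0.3, 0.4])
        with pytest.warns(UserWarning):
            pop = assemble_population(h, ev.target, threshold=0.0, evaluator=ev)
        assert len(pop) == 0

    def test_phenotype_mismatch_filtered_out(self):
        theta = np.full(9, 0.1)

        class WrongPhen(_FakeEvaluator):
            def metrics(self, theta):
                return bundle_matching(self.target, phenotype="DB")

        ev = WrongPhen(theta, phenotype="NDB")
        h = self._history_with([theta] * 4, [0.0] * 4)
        with pytest.warns(UserWarning):
            pop = assemble_population(h, ev.target, threshold=0.5, evaluator=ev)
        assert len(pop) == 0


class TestPrior:
    def test_default_prior_bounds(self):
        p = default_prior()
        assert np.all(p.lower == 0.0)
        assert p.upper[8] == 1e-3
        assert np.all(p.upper[:8] == 1.0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(lower=np.array([0.0, 1.0]), upper=np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            PriorSpec(lower=np.array([-0.1]), upper=np.array([1.0]))
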