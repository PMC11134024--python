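"""LICRSA operators and the bound-constrained optimizer."""

import math

import numpy as np
import pytest

from gazetune import licrsa
from gazetune.licrsa import (
    Crocodile,
    Dimension,
    LICRSAConfig,
    SearchSpace,
    cf_schedule,
    continuous_space,
    default_space,
    eliminate,
    encircle_update,
    hunt_update,
    interactive_crossover,
    levy_step,
    optimize,
    random_search,
)


def sphere(params):
    x = np.array(list(params.values()))
    return float((x * x).sum())


class TestLevy:
    @pytest.mark.parametrize("gamma", [2.5, 0.0, -1.0])
    def test_gamma_outside_domain_rejected(self, gamma):
        with pytest.raises(ValueError):
            levy_step(gamma, 3, np.random.default_rng(0))

    def test_deterministic_for_fixed_state(self):
        a = levy_step(1.5, 5, np.random.default_rng(9))
        b = levy_step(1.5, 5, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_heavier_tail_than_gaussian(self):
        rng = np.random.default_rng(0)
        draws = np.concatenate(
            [levy_step(1.5, 10_000, rng) for _ in range(10)]
        )
        tail = np.mean(np.abs(draws) > 10.0)
        gaussian_tail = 1.5e-23  # P(|Z| > 10) for a unit Gaussian
        assert tail >= 10 * gaussian_tail
        assert tail > 1e-4


class TestCFSchedule:
    def test_boundary_and_midpoint_values(self):
        assert cf_schedule(0, 40) == 1.0
        assert cf_schedule(40, 40) == 0.0
        assert cf_schedule(20, 40) == pytest.approx(0.5)

    def test_values_in_unit_interval(self):
        vals = [cf_schedule(l, 50) for l in range(51)]
        assert all(0.0 <= v <= 1.0 for v in vals)

    def test_iteration_beyond_tmax_rejected(self):
        with pytest.raises(ValueError):
            cf_schedule(41, 40)


def _population(n, d, seed):
    rng = np.random.default_rng(seed)
    return [Crocodile(y=rng.random(d), fitness=float(i)) for i in range(n)]


class TestPhaseUpdates:
    def test_positions_stay_in_unit_cube(self):
        cfg = LICRSAConfig(N=8, Tmax=40, seed=0)
        rng = np.random.default_rng(1)
        pop = _population(8, 2, seed=2)
        best = pop[0].y
        for l in range(1, 40):
            for c in pop:
                if l < 2 * cfg.Tmax / 4:
                    y = encircle_update(c, best, pop, l, cfg, rng)
                else:
                    y = hunt_update(c, best, pop, l, cfg, rng)
                assert (y >= 0).all() and (y <= 1).all()

    def test_updates_deterministic_for_fixed_state(self):
        cfg = LICRSAConfig(N=8, Tmax=40, seed=0)
        pop = _population(8, 3, seed=3)
        best = pop[1].y
        a = encircle_update(pop[0], best, pop, 2, cfg, np.random.default_rng(4))
        b = encircle_update(pop[0], best, pop, 2, cfg, np.random.default_rng(4))
        assert np.array_equal(a, b)

    def test_high_walk_with_degenerate_levy_term(self):
        # lam = 0 removes the Levy term: position = clip(best * (-phi) * mu)
        cfg = LICRSAConfig(N=8, Tmax=40, seed=0, lam=0.0)
        pop = _population(8, 3, seed=5)
        best = pop[2].y
        croc = pop[0]
        got = encircle_update(croc, best, pop, 1, cfg, np.random.default_rng(6))
        P = 0.1 + (croc.y - croc.y.mean()) / (best + cfg.epsilon)
        phi = best * P
        expected = np.clip(best * (-phi) * cfg.mu, 0.0, 1.0)
        assert np.allclose(got, expected, atol=1e-15)

    def test_cooperation_with_zero_coefficients_returns_best(self):
        cfg = LICRSAConfig(N=8, Tmax=40, seed=0, lam=0.0, epsilon=0.0)
        pop = _population(8, 3, seed=7)
        best = pop[3].y
        got = hunt_update(pop[0], best, pop, 35, cfg, np.random.default_rng(8))
        # phi * eps = 0 and RF * lam * levy = 0 (0/0 guarded by eps in RF is
        # irrelevant once multiplied by lam = 0)
        assert np.allclose(got, np.clip(best, 0, 1), atol=1e-12)

    def test_phase_preconditions_enforced(self):
        cfg = LICRSAConfig(N=8, Tmax=40, seed=0)
        pop = _population(8, 2, seed=9)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            encircle_update(pop[0], pop[0].y, pop, 25, cfg, rng)
        with pytest.raises(ValueError):
            hunt_update(pop[0], pop[0].y, pop, 5, cfg, rng)


class TestCrossover:
    def test_collapsed_population_moves_to_best_when_cf_is_one(self):
        cfg = LICRSAConfig(N=6, Tmax=40, seed=0)
        positions = np.tile(np.array([0.2, 0.8]), (6, 1))
        best = np.array([0.5, 0.5])
        out = interactive_crossover(positions, best, 0, cfg,
                                    np.random.default_rng(1))
        # CF(0) = 1 and the diversity terms vanish for identical pairs
        assert np.allclose(out, best)

    def test_cf_zero_identical_pairs_unchanged(self):
        cfg = LICRSAConfig(N=4, Tmax=40, seed=0)
        positions = np.tile(np.array([0.3, 0.6, 0.1]), (4, 1))
        out = interactive_crossover(positions, np.array([0.9, 0.9, 0.9]),
                                    40, cfg, np.random.default_rng(2))
        assert np.allclose(out, positions)

    def test_matches_straightline_transcription(self):
        cfg = LICRSAConfig(N=10, Tmax=40, seed=0)
        rng = np.random.default_rng(11)
        positions = rng.random((10, 3))
        best = rng.random(3)
        got = interactive_crossover(
            positions.copy(), best, 7, cfg, np.random.default_rng(42)
        )
        # independent transcription with an identically seeded generator
        r = np.random.default_rng(42)
        cf = (1 - 7 / 40) ** (2 * 7 / 40)
        perm = r.permutation(10)
        k1, k2 = perm[:5], perm[5:]
        c1 = r.random((5, 1))
        c2 = r.random((5, 1))
        expected = positions.copy()
        for i in range(5):
            a, b = positions[k1[i]], positions[k2[i]]
            expected[k1[i]] = a + cf * (best - a) + c1[i] * (a - b)
            expected[k2[i]] = b + cf * (best - b) + c2[i] * (b - a)
        expected = np.clip(expected, 0.0, 1.0)
        assert np.abs(got - expected).max() < 1e-12

    def test_odd_population_rejected(self):
        cfg = LICRSAConfig(N=4, Tmax=40, seed=0)
        with pytest.raises(ValueError):
            interactive_crossover(np.zeros((5, 2)), np.zeros(2), 1, cfg,
                                  np.random.default_rng(0))


class TestEliminate:
    @pytest.mark.parametrize(
        "f_old,f_new,keep_new",
        [(3.0, 2.0, True), (2.0, 3.0, False), (2.0, 2.0, False)],
    )
    def test_greedy_selection_truth_table(self, f_old, f_new, keep_new):
        old = Crocodile(y=np.zeros(2), fitness=f_old)
        new = Crocodile(y=np.ones(2), fitness=f_new)
        survivor = eliminate(old, new)
        assert survivor is (new if keep_new else old)


class TestOptimize:
    def test_sphere_converges(self):
        space = continuous_space([(-5, 5)] * 3)
        res = optimize(sphere, space, LICRSAConfig(N=20, Tmax=50, seed=1),
                       use_cache=False)
        assert res.best.fitness <= 1e-2

    def test_best_trace_monotone_nonincreasing(self):
        space = continuous_space([(-5, 5)] * 2)
        res = optimize(sphere, space, LICRSAConfig(N=8, Tmax=20, seed=2),
                       use_cache=False)
        assert len(res.trace) == 20
        assert all(a >= b for a, b in zip(res.trace, res.trace[1:]))

    def test_bitwise_reproducible_for_seed(self):
        space = continuous_space([(-5, 5)] * 2)
        cfg = LICRSAConfig(N=8, Tmax=12, seed=3)
        a = optimize(sphere, space, cfg, use_cache=False)
        b = optimize(sphere, space, cfg, use_cache=False)
        assert a.trace == b.trace
        assert np.array_equal(a.best.y, b.best.y)

    def test_plain_rsa_mode_runs_in_bounds(self):
        space = continuous_space([(-5, 5)] * 2)
        cfg = LICRSAConfig(N=8, Tmax=12, seed=4, crossover=False, levy=False)
        res = optimize(sphere, space, cfg, use_cache=False)
        assert (res.best.y >= 0).all() and (res.best.y <= 1).all()

    def test_nonfinite_fitness_penalized_with_warning(self):
        space = continuous_space([(0, 1)] * 2)

        def bad(params):
            x = np.array(list(params.values()))
            return math.nan if x[0] > 0.5 else float(x.sum())

        with pytest.warns(UserWarning, match="non-finite"):
            res = optimize(bad, space, LICRSAConfig(N=4, Tmax=4, seed=0),
                           use_cache=False)
        assert math.isfinite(res.best.fitness)

    def test_random_search_budget_and_trace(self):
        space = continuous_space([(-5, 5)] * 2)
        res = random_search(sphere, space, n_evaluations=30, seed=0)
        assert res.n_evaluations == 30
        assert len(res.trace) == 30
        assert all(a >= b for a, b in zip(res.trace, res.trace[1:]))


class TestSearchSpace:
    def test_decode_lower_and_upper_bounds(self):
        space = default_space()
        lo = space.decode(np.zeros(4))
        hi = space.decode(np.ones(4))
        assert lo == {"dropout": 0.1, "learning_rate": 0.003, "l2": 0.003,
                      "max_epoch": 5}
        assert hi == {"dropout": 0.4, "learning_rate": 0.1, "l2": 0.1,
                      "max_epoch": 20}

    def test_categorical_equal_width_bins(self):
        space = default_space()
        assert space.decode([0.1, 0.1, 0.1, 0.30])["max_epoch"] == 10

    def test_out_of_cube_position_clipped_with_warning(self):
        space = default_space()
        with pytest.warns(UserWarning, match="clipping"):
            decoded = space.decode(np.array([1.2, -0.1, 0.5, 0.5]))
        assert decoded["dropout"] == 0.4
        assert decoded["learning_rate"] == 0.003

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(name="x", kind="continuous", bounds=(1.0, 1.0)),
            dict(name="x", kind="continuous", bounds=(0.0, math.inf)),
            dict(name="x", kind="categorical", choices=()),
            dict(name="x", kind="other"),
        ],
    )
    def test_dimension_validation(self, kwargs):
        with pytest.raises(ValueError):
            Dimension(**kwargs)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(N=3), dict(N=5), dict(Tmax=3), dict(gamma=2.5), dict(gamma=0.0)],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LICRSAConfig(**kwargs)
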