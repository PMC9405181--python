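import numpy as np
import pytest
from dataclasses import replace

from dcsae.kha import (
    HyperparamSpace,
    KhaConfig,
    KrillSwarm,
    SpaceEntry,
    error_rate_fitness,
    food_position,
    foraging_motion,
    induced_motion,
    inertia_weight,
    kha_step,
    optimize,
    physical_diffusion,
    tune_dcsae,
)
from dcsae.model import DcsaeConfig, make_views, predict, train_dcsae

sphere = lambda x: float(np.sum(x**2))  # noqa: E731


def cfg5(seed=0, iters=100):
    return KhaConfig(np.full(5, -5.0), np.full(5, 5.0), n_krill=20,
                     max_iterations=iters, rng_seed=seed)


class TestInertiaAndDiffusion:
    def test_midpoint_inertia_is_half(self):
        c = KhaConfig(np.zeros(2), np.ones(2), max_iterations=100)
        assert inertia_weight(50, c) == pytest.approx(0.5)
        assert inertia_weight(0, c) == pytest.approx(0.9)
        assert inertia_weight(100, c) == pytest.approx(0.1)

    def test_diffusion_zero_at_final_iteration(self):
        c = KhaConfig(np.zeros(3), np.ones(3), max_iterations=40)
        d = physical_diffusion(40, c, np.random.default_rng(0))
        assert np.all(d == 0.0)

    def test_diffusion_bounded_and_deterministic(self):
        c = KhaConfig(np.zeros(3), np.ones(3), max_iterations=40)
        d1 = physical_diffusion(10, c, np.random.default_rng(9))
        d2 = physical_diffusion(10, c, np.random.default_rng(9))
        assert np.array_equal(d1, d2)
        assert np.abs(d1).max() <= c.diffusion_max


class TestInducedMotion:
    def test_zero_inertia_zero_alpha_gives_zero(self):
        c = KhaConfig(np.zeros(2), np.ones(2), n_krill=3, max_iterations=10,
                      inertia_start=0.0, inertia_end=0.0, n_max=0.0)
        swarm = KrillSwarm.init(c, sphere, np.random.default_rng(0))
        n = induced_motion(swarm, 5, c, np.random.default_rng(0))
        assert np.all(n == 0.0)

    def test_best_control_coefficient_bounds(self):
        # C_best = 2(rand + I/I_max) lands in [2, 4] at the final iteration
        c = KhaConfig(np.zeros(1), np.ones(1), max_iterations=10)
        for seed in range(5):
            r = np.random.default_rng(seed).uniform()
            assert 2.0 <= 2.0 * (r + 1.0) <= 4.0


class TestForaging:
    def test_food_is_inverse_fitness_weighted_centroid(self):
        c = KhaConfig(np.zeros(1), np.ones(1), n_krill=2)
        swarm = KrillSwarm(
            positions=np.array([[0.0], [1.0]]),
            fitness=np.array([1.0, 3.0]),
            induced=np.zeros((2, 1)),
            foraging=np.zeros((2, 1)),
            best_position=np.array([0.0]),
            best_fitness=1.0,
        )
        assert food_position(swarm)[0] == pytest.approx(0.25, abs=1e-9)

    def test_degenerate_swarm_food_at_common_point(self):
        c = KhaConfig(np.zeros(2), np.ones(2), n_krill=4)
        pos = np.tile([0.3, 0.7], (4, 1))
        swarm = KrillSwarm(pos, np.ones(4), np.zeros((4, 2)), np.zeros((4, 2)),
                           pos[0].copy(), 1.0)
        assert np.allclose(food_position(swarm), [0.3, 0.7])

    def test_zero_speed_zero_inertia_gives_zero(self):
        c = KhaConfig(np.zeros(2), np.ones(2), n_krill=3, max_iterations=10,
                      foraging_speed=0.0, foraging_inertia_start=0.0,
                      foraging_inertia_end=0.0)
        swarm = KrillSwarm.init(c, sphere, np.random.default_rng(1))
        f = foraging_motion(swarm, food_position(swarm), 5, c)
        assert np.all(f == 0.0)


class TestKhaStep:
    def test_null_field_leaves_positions(self):
        c = KhaConfig(np.full(2, -1.0), np.ones(2), n_krill=3, max_iterations=10,
                      n_max=0.0, inertia_start=0.0, inertia_end=0.0,
                      foraging_speed=0.0, foraging_inertia_start=0.0,
                      foraging_inertia_end=0.0, diffusion_max=0.0)
        swarm = KrillSwarm.init(c, sphere, np.random.default_rng(2))
        before = swarm.positions.copy()
        kha_step(swarm, 5, c, sphere, np.random.default_rng(2))
        assert np.array_equal(swarm.positions, before)

    def test_incumbent_never_worsens_and_bounds_hold(self):
        c = cfg5(seed=4, iters=30)
        rng = np.random.default_rng(4)
        swarm = KrillSwarm.init(c, sphere, rng)
        prev = swarm.best_fitness
        for it in range(1, 31):
            kha_step(swarm, it, c, sphere, rng)
            assert swarm.best_fitness <= prev
            prev = swarm.best_fitness
            assert swarm.positions.min() >= -5.0 and swarm.positions.max() <= 5.0


class TestOptimize:
    def test_sphere_benchmark(self):
        hits = sum(optimize(sphere, cfg5(seed))[1] < 1e-2 for seed in range(3))
        assert hits == 3

    def test_deterministic_trace(self):
        _, c1, t1 = optimize(sphere, cfg5(7, iters=30))
        _, c2, t2 = optimize(sphere, cfg5(7, iters=30))
        assert t1 == t2 and c1 == c2

    def test_quadratic_progress_over_iterations(self):
        quad = lambda x: float((x[0] - 0.3) ** 2 + 2 * (x[1] + 0.1) ** 2)  # noqa: E731
        early, late = [], []
        for seed in range(5):
            c = KhaConfig(np.full(2, -2.0), np.full(2, 2.0), n_krill=10,
                          max_iterations=100, rng_seed=seed)
            _, _, trace = optimize(quad, c)
            early.append(trace[10])
            late.append(trace[100])
        assert np.mean(late) < np.mean(early)


class TestErrorRateFitness:
    @pytest.mark.parametrize(
        "wrong,total,expected", [(3, 100, 3.0), (0, 50, 0.0), (20, 20, 100.0)]
    )
    def test_percentage(self, wrong, total, expected):
        actual = np.zeros(total, dtype=int)
        predicted = actual.copy()
        predicted[:wrong] = 1
        assert error_rate_fitness(predicted, actual) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            error_rate_fitness(np.zeros(3), np.zeros(4))


class TestHyperparamSpace:
    def test_log_scale_decode_endpoints(self):
        e = SpaceEntry("learning_rate", 1e-4, 1e-1, scale="log")
        assert e.decode(0.0) == pytest.approx(1e-4)
        assert e.decode(1.0) == pytest.approx(1e-1)
        assert e.decode(0.5) == pytest.approx(10 ** -2.5)

    def test_integer_rounding_half_up(self):
        e = SpaceEntry("first_hidden_f", 8, 64, kind="integer")
        assert e.decode(0.0) == 8 and e.decode(1.0) == 64
        assert isinstance(e.decode(0.5), int)

    def test_degenerate_space_passes_value_through(self, small_table):
        norm, _ = small_table
        space = HyperparamSpace([SpaceEntry("learning_rate", 0.02, 0.02)])
        kcfg = KhaConfig(np.zeros(1), np.ones(1), n_krill=2, max_iterations=1,
                         rng_seed=0)
        base = DcsaeConfig(rng_seed=0)
        best, _, _, _ = tune_dcsae(norm.values, norm.labels, space, kcfg, base,
                                   inner_epochs=2)
        assert best.learning_rate == pytest.approx(0.02)


class TestTuneDcsae:
    def test_tuned_not_worse_than_default_on_fixed_split(self, small_table):
        norm, _ = small_table
        space = HyperparamSpace([SpaceEntry("learning_rate", 1e-4, 1e-1, scale="log")])
        kcfg = KhaConfig(np.zeros(1), np.ones(1), n_krill=6, max_iterations=8,
                         rng_seed=0)
        base = DcsaeConfig(rng_seed=0)
        best_cfg, best_err, trace, _ = tune_dcsae(
            norm.values, norm.labels, space, kcfg, base,
            validation_fraction=0.25, inner_epochs=10,
        )
        # reproduce the tuner's held-out split for the untuned reference
        rng = np.random.default_rng(kcfg.rng_seed)
        perm = rng.permutation(norm.n_samples)
        n_val = max(1, round(0.25 * norm.n_samples))
        val, tr = perm[:n_val], perm[n_val:]
        cfg0 = replace(base, epochs=10)
        m0 = train_dcsae(make_views(norm.values[tr], norm.labels[tr]), cfg0)
        p0, _ = predict(m0, norm.values[val])
        default_err = error_rate_fitness(p0, norm.labels[val])
        assert best_err <= default_err
        assert all(a >= b for a, b in zip(trace, trace[1:]))
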