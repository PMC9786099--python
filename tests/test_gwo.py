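import numpy as np
import pytest

from igwo.config import OptimizerConfig
from igwo.gwo import (
    LeaderTriplet,
    coefficient_schedule,
    draw_coefficients,
    leader_guided_update,
    run_gwo,
)


def make_triplet(alpha, beta, delta, fitnesses=(3.0, 2.0, 1.0)):
    return LeaderTriplet(
        np.asarray(alpha, dtype=float),
        np.asarray(beta, dtype=float),
        np.asarray(delta, dtype=float),
        *fitnesses,
    )


class TestCoefficientSchedule:
    @pytest.mark.parametrize(
        "t, T, expected", [(0, 100, 2.0), (100, 100, 0.0), (50, 100, 1.0)])
    def test_endpoints_and_midpoint(self, t, T, expected):
        assert coefficient_schedule(t, T) == expected

    @pytest.mark.parametrize("t, T", [(-1, 10), (11, 10), (0, 0), (0, -5)])
    def test_invalid_inputs(self, t, T):
        with pytest.raises(ValueError):
            coefficient_schedule(t, T)

    def test_fractional_midpoint(self):
        assert coefficient_schedule(0.5, 1) == 1.0


class TestDrawCoefficients:
    def test_a_zero_degenerates(self, rng):
        A, C = draw_coefficients(0.0, 5, rng)
        assert np.all(A == 0.0)

    def test_monte_carlo_ranges(self):
        rng = np.random.default_rng(7)
        A = np.concatenate([draw_coefficients(2.0, 10, rng)[0] for _ in range(1000)])
        rng = np.random.default_rng(7)
        C = np.concatenate([draw_coefficients(2.0, 10, rng)[1] for _ in range(1000)])
        assert A.min() < -1.95 and A.max() > 1.95
        assert np.all((A >= -2.0) & (A < 2.0))
        assert C.min() < 0.05 and C.max() > 1.95
        assert np.all((C >= 0.0) & (C < 2.0))

    def test_seed_determinism(self):
        first = draw_coefficients(1.5, 4, np.random.default_rng(3))
        second = draw_coefficients(1.5, 4, np.random.default_rng(3))
        assert np.array_equal(first[0], second[0])
        assert np.array_equal(first[1], second[1])

    def test_invalid_scale(self, rng):
        with pytest.raises(ValueError):
            draw_coefficients(2.5, 3, rng)


class TestLeaderGuidedUpdate:
    def test_fixed_point_when_A_vanishes(self, rng):
        x = np.array([0.3, 0.7])
        leaders = make_triplet(x, x, x)
        out = leader_guided_update(x, leaders, a=0.0, rng=rng)
        assert np.allclose(out, x)

    def test_hand_worked_example(self):
        # X=(0,0), leaders (1,0),(0,1),(0,0); A=0, C=1 for every leader:
        # candidates are the leader positions themselves, mean = (1/3, 1/3)
        zero = np.zeros(2)
        one = np.ones(2)
        leaders = make_triplet([1, 0], [0, 1], [0, 0])
        coeffs = [(zero, one)] * 3
        out = leader_guided_update(np.zeros(2), leaders, coefficients=coeffs)
        assert np.allclose(out, [1 / 3, 1 / 3])

    def test_clamping(self, rng):
        leaders = make_triplet([5, 5], [4, 4], [3, 3])
        for _ in range(100):
            out = leader_guided_update(
                rng.random(2), leaders, a=2.0, rng=rng,
                domain_low=0.0, domain_high=1.0)
            assert np.all(out >= 0.0) and np.all(out <= 1.0)

    def test_dimension_mismatch(self, rng):
        leaders = make_triplet([1, 0, 0], [0, 1, 0], [0, 0, 1])
        with pytest.raises(ValueError):
            leader_guided_update(np.zeros(2), leaders, a=1.0, rng=rng)

    def test_oracle_equivalence(self):
        # straight-line transcription of the update equations, computed
        # independently of the implementation
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.uniform(-5, 5, 5)
            leader_positions = [rng.uniform(-5, 5, 5) for _ in range(3)]
            coeffs = [(rng.uniform(-2, 2, 5), rng.uniform(0, 2, 5)) for _ in range(3)]
            expected = np.zeros(5)
            for (lead, (A, C)) in zip(leader_positions, coeffs):
                D = np.abs(C * lead - x)
                expected += lead - A * D
            expected = np.clip(expected / 3.0, -10.0, 10.0)
            got = leader_guided_update(
                x, make_triplet(*leader_positions), coefficients=coeffs,
                domain_low=-10.0, domain_high=10.0)
            assert np.all(np.abs(got - expected) < 1e-12)


class TestRunGwo:
    def test_constant_objective(self, small_config):
        result = run_gwo(lambda x: 7.0, small_config)
        assert result.best_fitness == 7.0
        assert np.all(result.history == 7.0)

    def test_sphere_convergence(self, sphere_objective):
        config = OptimizerConfig(
            dimensionality=2, domain_low=-1.0, domain_high=1.0,
            orientation="minimize", seed=0, sharing_radius="off")
        result = run_gwo(sphere_objective, config)
        assert result.best_fitness <= 1e-2

    def test_history_monotone_minimize(self, sphere_objective):
        config = OptimizerConfig(
            dimensionality=3, domain_low=-1.0, domain_high=1.0,
            orientation="minimize", seed=5, sharing_radius="off", iterations=30)
        history = run_gwo(sphere_objective, config).history
        assert len(history) == 30
        assert np.all(np.diff(history) <= 0)

    def test_history_monotone_maximize(self):
        config = OptimizerConfig(dimensionality=2, seed=2, iterations=20)
        history = run_gwo(lambda x: float(np.sum(x)), config).history
        assert np.all(np.diff(history) >= 0)

    def test_seed_determinism(self, sphere_objective):
        config = OptimizerConfig(
            dimensionality=2, domain_low=-1.0, domain_high=1.0,
            orientation="minimize", seed=11, iterations=25)
        first = run_gwo(sphere_objective, config)
        second = run_gwo(sphere_objective, config)
        assert np.array_equal(first.history, second.history)
        assert np.array_equal(first.best_position, second.best_position)

    def test_population_too_small(self, sphere_objective):
        with pytest.raises(Exception):
            OptimizerConfig(population_size=2)

    def test_non_finite_objective(self, small_config):
        with pytest.raises(ValueError, match="non-finite"):
            run_gwo(lambda x: float("nan"), small_config)

    def test_positions_stay_in_domain(self):
        seen = []

        def spy(x):
            seen.append(np.array(x))
            return float(np.sum(x**2))

        config = OptimizerConfig(
            dimensionality=4, domain_low=-0.5, domain_high=0.5,
            orientation="minimize", seed=1, iterations=100)
        run_gwo(spy, config)
        stacked = np.vstack(seen)
        assert np.all(stacked >= -0.5) and np.all(stacked <= 0.5)

    def test_initial_positions_shape_checked(self, sphere_objective, small_config):
        bad = np.zeros((2, small_config.dimensionality))
        with pytest.raises(ValueError, match="shape"):
            run_gwo(sphere_objective, small_config, initial_positions=bad)

    def test_sharing_increases_population_spread(self):
        # Two equal peaks at 0.25 and 0.75. The averaging update collapses
        # the pack either way, but niche-penalized leader ranking keeps the
        # population measurably more spread out along the way.
        def bimodal(x):
            return float(np.exp(-((x[0] - 0.25) / 0.1) ** 2)
                         + np.exp(-((x[0] - 0.75) / 0.1) ** 2))

        def mean_spread(sharing_radius):
            spreads = []
            for seed in range(10):
                config = OptimizerConfig(
                    dimensionality=1, seed=seed, sharing_radius=sharing_radius,
                    iterations=100)
                seen = []
                calls = [0]

                def spy(x):
                    seen.append(float(x[0]))
                    return bimodal(x)

                run_gwo(spy, config)
                pops = np.array(seen).reshape(-1, config.population_size)
                spreads.append(pops.std(axis=1).mean())
            return np.mean(spreads)

        assert mean_spread(0.3) > mean_spread("off")
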