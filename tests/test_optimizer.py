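"""Goshawk optimizer: chaos map, phase updates, greedy monotonicity."""

import numpy as np
import pytest

from fermsense import (
    BENCHMARKS,
    OptimizerConfig,
    SearchSpace,
    attack_radius,
    cosine_factor,
    cubic_map_sequence,
    init_population,
    ngo_phase1_update,
    ngo_phase2_update,
    optimize,
    random_diff_perturbation,
    sine_cosine_update,
)


class StubRng:
    """Deterministic rng stand-in: fixed value for every draw."""

    def __init__(self, r_val=0.0):
        self.r_val = r_val

    def random(self, size=None):
        return np.full(size, self.r_val) if size is not None else self.r_val

    def integers(self, lo, hi, size=None):
        return np.full(size, lo, dtype=int) if size is not None else lo

    def uniform(self, lo, hi, size=None):
        return np.full(size, lo) if size is not None else lo


class RecordingRng:
    """Pass-through rng that records every integers/random draw."""

    def __init__(self, seed):
        self._rng = np.random.default_rng(seed)
        self.int_draws = []
        self.float_draws = []

    def random(self, size=None):
        out = self._rng.random(size)
        self.float_draws.append(np.ravel(out))
        return out

    def integers(self, lo, hi, size=None):
        out = self._rng.integers(lo, hi, size)
        self.int_draws.append((lo, hi, np.ravel(out)))
        return out


class TestCubicMap:
    def test_hand_iterate(self):
        x1 = cubic_map_sequence(0.3, rho=2.595, count=1)[0]
        assert x1 == pytest.approx(2.595 * 0.3 * (1 - 0.09), abs=1e-12)

    @pytest.mark.parametrize("x0", [0.0, 1.0, -0.2, 1.4])
    def test_rejects_boundary_and_outside_seeds(self, x0):
        with pytest.raises(ValueError):
            cubic_map_sequence(x0)

    def test_long_orbit_stays_in_unit_interval(self):
        seq = cubic_map_sequence(0.37, rho=2.595, count=10_000)
        assert np.all((seq > 0) & (seq < 1))


class TestInitPopulation:
    def test_within_bounds_and_reproducible(self):
        space = SearchSpace(np.array([-3.0, 0.0]), np.array([2.0, 10.0]))
        for variant in ("ngo", "ingo"):
            cfg = OptimizerConfig(pop_size=20, variant=variant, seed=5)
            p1, p2 = init_population(space, cfg), init_population(space, cfg)
            np.testing.assert_array_equal(p1, p2)
            assert np.all(p1 >= space.lower) and np.all(p1 <= space.upper)

    def test_chaotic_init_disperses_at_least_as_much(self):
        space = SearchSpace(np.zeros(2), np.ones(2))
        spans = {"ngo": 0.0, "ingo": 0.0}
        for variant in spans:
            for seed in range(50):
                cfg = OptimizerConfig(pop_size=30, variant=variant, seed=seed)
                pop = init_population(space, cfg)
                spans[variant] += float(np.mean(pop.max(0) - pop.min(0)))
        assert spans["ingo"] >= spans["ngo"]


class TestPhaseUpdates:
    def test_phase1_zero_step_keeps_positions(self, rng):
        pop = rng.normal(size=(6, 3))
        fit = rng.random(6)
        cand = ngo_phase1_update(pop, fit, StubRng(r_val=0.0))
        np.testing.assert_allclose(cand, pop)

    def test_phase1_needs_two_individuals(self, rng):
        with pytest.raises(ValueError):
            ngo_phase1_update(rng.normal(size=(1, 2)), np.zeros(1), StubRng())

    def test_phase1_sampling_distributions(self):
        rec = RecordingRng(0)
        pop = np.random.default_rng(9).normal(size=(50, 10))
        fit = np.arange(50.0)
        for _ in range(200):
            ngo_phase1_update(pop, fit, rec)
        intensity = np.concatenate(
            [v for lo, hi, v in rec.int_draws if (lo, hi) == (1, 3)]
        )
        steps = np.concatenate(rec.float_draws)
        assert intensity.size >= 1e5 and steps.size >= 1e5
        assert abs(np.mean(intensity == 1) - 0.5) < 0.01
        assert np.all((steps >= 0) & (steps < 1))
        assert abs(np.mean(steps < 0.5) - 0.5) < 0.01

    def test_attack_radius_decay(self):
        assert attack_radius(0, 100) == pytest.approx(0.02)
        assert attack_radius(100, 100) == 0.0
        assert attack_radius(50, 100) == pytest.approx(0.01)
        with pytest.raises(ValueError):
            attack_radius(101, 100)

    def test_phase2_final_iteration_is_identity(self, rng):
        pop = rng.normal(size=(5, 2))
        cand = ngo_phase2_update(pop, np.zeros(5), t=10, T=10, rng=StubRng(0.5))
        np.testing.assert_allclose(cand, pop)

    def test_phase2_relative_change_bounded_by_radius(self, rng):
        pop = rng.normal(size=(8, 3)) + 2.0
        t, T = 3, 10
        cand = ngo_phase2_update(pop, np.zeros(8), t, T, np.random.default_rng(0))
        rel = np.abs(cand - pop) / np.abs(pop)
        assert np.all(rel <= attack_radius(t, T) + 1e-12)

    def test_cosine_factor_endpoints_and_monotonicity(self):
        assert cosine_factor(0, 50, 0.4, 0.9) == pytest.approx(0.9)
        assert cosine_factor(50, 50, 0.4, 0.9) == pytest.approx(0.5 * 0.5 + 0.4)
        vals = [cosine_factor(t, 50, 0.4, 0.9) for t in range(51)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_sine_cosine_zero_weight_is_identity(self, rng):
        pop = rng.normal(size=(6, 2))
        cand = sine_cosine_update(pop, rng.random(6), omega=0.0, rng=StubRng(0.3))
        np.testing.assert_allclose(cand, pop)

    def test_sine_cosine_full_weight_zero_sine_collapses(self, rng):
        # omega=1 with sin(r1)=0 (r1 drawn as 0) leaves only the vanished
        # attraction term for the improving branch
        pop = np.abs(rng.normal(size=(4, 2)))
        fit = np.array([3.0, 2.0, 1.0, 0.0])
        cand = sine_cosine_update(pop, fit, omega=1.0, rng=StubRng(0.0))
        # StubRng draws r1=0 via uniform -> sin=0; prey index lo=1 shifts by 1
        prey_better = fit[(np.arange(4) + 1) % 4] < fit
        np.testing.assert_allclose(cand[prey_better], 0.0, atol=1e-12)

    def test_diff_perturbation_degenerate_and_forced(self, rng):
        x = rng.normal(size=3)
        np.testing.assert_allclose(
            random_diff_perturbation(x, x, x, np.random.default_rng(0)), 0.0
        )
        best, xi, xr = rng.normal(size=(3, 4))
        cand = random_diff_perturbation(best, xi, xr, StubRng(1.0))
        np.testing.assert_allclose(cand, (best - xi) + (xr - xi))


class TestOptimize:
    space = SearchSpace(np.array([-5.0, -5.0]), np.array([5.0, 5.0]))

    @pytest.mark.parametrize("variant", ["ngo", "ingo"])
    def test_history_nonincreasing_and_reproducible(self, variant):
        cfg = OptimizerConfig(pop_size=10, max_iter=30, variant=variant, seed=7)
        run1 = optimize(BENCHMARKS["sphere"][0], self.space, cfg)
        run2 = optimize(BENCHMARKS["sphere"][0], self.space, cfg)
        assert np.all(np.diff(run1.history) <= 0)
        assert run1.best_f == run1.history[-1]
        np.testing.assert_array_equal(run1.best_x, run2.best_x)
        np.testing.assert_array_equal(run1.history, run2.history)

    def test_positions_respect_bounds(self):
        seen = []

        def fitness(x):
            seen.append(x.copy())
            return float(np.sum(x**2))

        cfg = OptimizerConfig(pop_size=6, max_iter=10, variant="ingo", seed=3)
        optimize(fitness, self.space, cfg)
        pts = np.array(seen)
        assert np.all(pts >= self.space.lower) and np.all(pts <= self.space.upper)

    def test_nonfinite_fitness_raises(self):
        def bad(x):
            return np.nan

        with pytest.raises(ValueError, match="non-finite"):
            optimize(bad, self.space, OptimizerConfig(pop_size=4, max_iter=2, seed=0))
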