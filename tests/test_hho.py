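"""Unit and property tests of the Harris Hawks optimizer primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gamma as scipy_gamma

from hhosvr import hho


class QueuedRng:
    """Feeds predetermined uniform draws, delegating everything else."""

    def __init__(self, values, seed=0):
        self.values = list(values)
        self._rng = np.random.default_rng(seed)

    def random(self, size=None):
        if size is None and self.values:
            return self.values.pop(0)
        return self._rng.random(size)

    def integers(self, *args, **kwargs):
        return self._rng.integers(*args, **kwargs)


def sphere(x):
    return float(np.sum(np.square(x)))


UNIT_SQUARE = hho.SearchSpace([0.0, 0.0], [1.0, 1.0])


class TestSearchSpace:
    def test_rejects_inverted_or_mismatched_bounds(self):
        with pytest.raises(ValueError):
            hho.SearchSpace([1.0], [1.0])
        with pytest.raises(ValueError):
            hho.SearchSpace([0.0, 0.0], [1.0])

    def test_clip_repairs_out_of_box(self):
        assert np.allclose(UNIT_SQUARE.clip([-1.0, 2.0]), [0.0, 1.0])


class TestInitPopulation:
    def test_positions_within_bounds_and_rabbit_is_argmin(self, rng):
        cfg = hho.HhoConfig(n_hawks=30, seed=1)
        pop, n_evals = hho.init_population(UNIT_SQUARE, cfg, rng, sphere)
        assert pop.positions.shape == (30, 2)
        assert np.all(pop.positions >= 0.0) and np.all(pop.positions <= 1.0)
        assert n_evals == 30
        assert pop.rabbit_fitness == pytest.approx(pop.fitness.min())

    def test_constant_objective_sets_rabbit_to_constant(self, rng):
        pop, _ = hho.init_population(
            UNIT_SQUARE, hho.HhoConfig(n_hawks=5), rng, lambda x: 5.0
        )
        assert pop.rabbit_fitness == 5.0

    def test_fixed_seed_reproduces_population_bitwise(self):
        cfg = hho.HhoConfig(n_hawks=10, seed=7)
        pop1, _ = hho.init_population(UNIT_SQUARE, cfg, np.random.default_rng(7), sphere)
        pop2, _ = hho.init_population(UNIT_SQUARE, cfg, np.random.default_rng(7), sphere)
        assert np.array_equal(pop1.positions, pop2.positions)
        assert np.array_equal(pop1.fitness, pop2.fitness)

    def test_non_finite_objective_is_flagged_with_position(self, rng):
        with pytest.raises(hho.ObjectiveError):
            hho.init_population(
                UNIT_SQUARE, hho.HhoConfig(n_hawks=3), rng, lambda x: float("nan")
            )


class TestMeanPosition:
    def test_two_point_mean_and_identity(self):
        pop = hho.HawkPopulation(
            positions=np.array([[0.0, 0.0], [2.0, 4.0]]),
            fitness=np.zeros(2),
            rabbit_position=np.zeros(2),
            rabbit_fitness=0.0,
        )
        assert np.allclose(hho.mean_position(pop), [1.0, 2.0])
        single = hho.HawkPopulation(
            positions=np.array([[3.0, 1.0, 2.0]]),
            fitness=np.zeros(1),
            rabbit_position=np.zeros(3),
            rabbit_fitness=0.0,
        )
        assert np.allclose(hho.mean_position(single), [3.0, 1.0, 2.0])

    def test_matches_elementwise_summation_oracle(self, rng):
        X = rng.normal(size=(5, 3))
        pop = hho.HawkPopulation(
            positions=X, fitness=np.zeros(5), rabbit_position=np.zeros(3), rabbit_fitness=0.0
        )
        expected = [sum(X[i, d] for i in range(5)) / 5.0 for d in range(3)]
        assert np.allclose(hho.mean_position(pop), expected, atol=1e-15)


class TestEscapeEnergy:
    @pytest.mark.parametrize(
        "e0,t,T,expected",
        [(0.9, 50, 50, 0.0), (1.0, 0, 50, 2.0), (-0.4, 25, 50, -0.4)],
    )
    def test_linear_decay_values(self, e0, t, T, expected):
        assert hho.escape_energy(e0, t, T) == pytest.approx(expected)

    def test_zero_budget_is_an_error(self):
        with pytest.raises(ValueError):
            hho.escape_energy(0.5, 0, 0)

    @settings(max_examples=50, derandomize=True)
    @given(
        e0=st.floats(-1.0, 1.0, exclude_min=True, exclude_max=True),
        t=st.integers(0, 100),
    )
    def test_energy_envelope(self, e0, t):
        e = hho.escape_energy(e0, t, 100)
        assert abs(e) <= 2.0 * abs(e0) * (1.0 - t / 100) + 1e-12
        assert abs(e) <= 2.0 * (1.0 - t / 100) + 1e-12


class TestLevyStep:
    def test_scale_constant_matches_independent_gamma_evaluation(self):
        beta = 1.5
        expected = (
            scipy_gamma(1 + beta)
            * math.sin(math.pi * beta / 2)
            / (scipy_gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
        ) ** (1 / beta)
        assert hho.levy_scale(beta) == pytest.approx(expected, rel=1e-12)

    def test_shape_and_finiteness(self, rng):
        step = hho.levy_step(7, 1.5, rng)
        assert step.shape == (7,)
        assert np.all(np.isfinite(step))

    def test_zero_u_gives_zero_component_and_zero_v_is_redrawn(self):
        class ArrayQueue:
            """Returns queued arrays for sized draws (u first, then v draws)."""

            def __init__(self, arrays):
                self.arrays = [np.asarray(a, dtype=float) for a in arrays]

            def random(self, size=None):
                out = self.arrays.pop(0)
                return out if size is not None else float(out)

        # u = 0 in one component forces that step component to zero
        step = hho.levy_step(2, 1.5, ArrayQueue([[0.0, 0.5], [0.4, 0.4]]))
        assert step[0] == 0.0 and step[1] > 0.0
        # v = 0 triggers a redraw instead of dividing by zero
        step = hho.levy_step(2, 1.5, ArrayQueue([[0.5, 0.5], [0.0, 0.4], [0.7]]))
        assert np.all(np.isfinite(step)) and np.all(step > 0.0)


class TestMoves:
    def test_exploration_far_branch_with_zero_coefficient_returns_rand_hawk(self):
        rng = QueuedRng([0.9, 0.0, 0.3])  # q >= 0.5, r1 = 0
        rand_hawk = np.array([0.2, 0.8])
        out = hho.exploration_move(
            np.array([0.5, 0.5]), rand_hawk, np.array([0.1, 0.1]),
            np.array([0.4, 0.4]), UNIT_SQUARE, rng,
        )
        assert np.allclose(out, rand_hawk)

    def test_exploration_near_branch_zero_coefficient_and_clipping(self):
        space = hho.SearchSpace([0.0], [10.0])
        rabbit, mean = np.array([5.0]), np.array([3.0])
        out = hho.exploration_move(
            np.array([1.0]), np.array([2.0]), rabbit, mean, space, QueuedRng([0.1, 0.0, 0.5])
        )
        assert np.allclose(out, [2.0])  # r3 = 0: rabbit - mean
        out = hho.exploration_move(
            np.array([1.0]), np.array([2.0]), rabbit, mean, space, QueuedRng([0.1, 1.0, 0.5])
        )
        # raw (5-3) - 1*(0 + 0.5*10) = -3, clipped to the lower bound
        assert np.allclose(out, [0.0])

    def test_soft_besiege_zero_energy_reduces_to_pursuit_vector(self):
        out = hho.soft_besiege_move(np.array([1.0, 2.0]), np.array([3.0, 5.0]), 0.0, 1.3)
        assert np.allclose(out, [2.0, 3.0])

    def test_soft_besiege_hand_arithmetic(self):
        out = hho.soft_besiege_move(np.array([2.0]), np.array([3.0]), 1.0, 0.0)
        assert np.allclose(out, [-1.0])  # (3-2) - |0-2|

    def test_soft_besiege_vectorization_matches_scalar_loop(self, rng):
        hawk, rabbit = rng.normal(size=4), rng.normal(size=4)
        e, j = 0.7, 1.2
        vec = hho.soft_besiege_move(hawk, rabbit, e, j)
        scalar = [
            (rabbit[d] - hawk[d]) - e * abs(j * rabbit[d] - hawk[d]) for d in range(4)
        ]
        assert np.allclose(vec, scalar, atol=1e-15)

    @pytest.mark.parametrize(
        "hawk,rabbit,e,expected",
        [(1.0, 4.0, 1.0, 1.0), (0.0, 2.0, -0.5, 3.0), (7.0, 7.0, 0.0, 7.0)],
    )
    def test_hard_besiege_hand_arithmetic(self, hawk, rabbit, e, expected):
        out = hho.hard_besiege_move(np.array([hawk]), np.array([rabbit]), e)
        assert np.allclose(out, [expected])


class TestDives:
    def test_soft_dive_adopts_improving_first_candidate(self):
        # E = 0 forces Y = rabbit; the rabbit is strictly better than the hawk
        hawk = np.array([3.0, 3.0])
        rabbit = np.array([1.0, 1.0])
        space = hho.SearchSpace([-5.0, -5.0], [5.0, 5.0])
        pos, fit, evals = hho.soft_besiege_dive(
            hawk, sphere(hawk), rabbit, 0.0, 1.0, sphere, space, np.random.default_rng(0)
        )
        assert np.allclose(pos, rabbit)
        assert fit == pytest.approx(2.0)
        assert evals == 2

    def test_dive_retains_position_when_no_candidate_improves(self):
        hawk = np.zeros(2)  # already optimal for the sphere
        space = hho.SearchSpace([-5.0, -5.0], [5.0, 5.0])
        pos, fit, evals = hho.soft_besiege_dive(
            hawk, 0.0, np.array([2.0, 2.0]), 0.9, 1.5, sphere, space, np.random.default_rng(1)
        )
        assert np.allclose(pos, hawk)
        assert fit == 0.0
        assert evals == 2

    def test_hard_dive_energy_zero_jumps_to_rabbit_when_better(self):
        hawk = np.array([4.0, 4.0])
        rabbit = np.array([0.5, 0.5])
        space = hho.SearchSpace([-5.0, -5.0], [5.0, 5.0])
        pos, fit, _ = hho.hard_besiege_dive(
            hawk, sphere(hawk), rabbit, np.array([2.0, 2.0]), 0.0, 1.0,
            sphere, space, np.random.default_rng(2),
        )
        assert np.allclose(pos, rabbit)

    def test_hard_dive_target_formula_matches_component_loop(self, rng):
        hawk = rng.normal(size=4)
        rabbit = rng.normal(size=4)
        mean_pos = rng.normal(size=4)
        e, j = 0.3, 0.8
        expected = [rabbit[d] - e * abs(j * rabbit[d] - mean_pos[d]) for d in range(4)]
        space = hho.SearchSpace([-100.0] * 4, [100.0] * 4)
        captured = []

        def capture(x):
            captured.append(x.copy())
            return sphere(x)

        hho.hard_besiege_dive(
            hawk, 1e9, rabbit, mean_pos, e, j, capture, space, np.random.default_rng(3)
        )
        assert np.allclose(captured[0], expected, atol=1e-14)


class TestHhoOptimize:
    def test_constant_objective_gives_flat_convergence(self):
        result = hho.hho_optimize(
            lambda x: 3.25, UNIT_SQUARE, hho.HhoConfig(n_hawks=5, max_iter=10, seed=0)
        )
        assert result.best_fitness == 3.25
        assert np.all(result.convergence == 3.25)

    def test_one_dimensional_quadratic_recovery_across_seeds(self):
        space = hho.SearchSpace([0.0], [10.0])
        hits = 0
        for seed in range(10):
            res = hho.hho_optimize(
                lambda x: (x[0] - 3.0) ** 2,
                space,
                hho.HhoConfig(n_hawks=30, max_iter=100, seed=seed),
            )
            if abs(res.best_position[0] - 3.0) < 0.01:
                hits += 1
        assert hits >= 9

    def test_every_evaluated_position_is_within_bounds(self):
        space = hho.SearchSpace([-10.0, -10.0], [10.0, 10.0])
        seen = []

        def watched(x):
            seen.append(x.copy())
            return sphere(x)

        hho.hho_optimize(watched, space, hho.HhoConfig(n_hawks=10, max_iter=30, seed=4))
        stacked = np.vstack(seen)
        assert np.all(stacked >= -10.0) and np.all(stacked <= 10.0)

    def test_convergence_is_monotone_and_consistent(self):
        space = hho.SearchSpace([-10.0, -10.0], [10.0, 10.0])
        res = hho.hho_optimize(sphere, space, hho.HhoConfig(n_hawks=10, max_iter=50, seed=5))
        assert np.all(np.diff(res.convergence) <= 0)
        assert res.best_fitness == res.convergence[-1]

    def test_seed_determinism_of_full_result(self):
        space = hho.SearchSpace([-10.0, -10.0], [10.0, 10.0])
        cfg = hho.HhoConfig(n_hawks=8, max_iter=20, seed=11)
        a = hho.hho_optimize(sphere, space, cfg)
        b = hho.hho_optimize(sphere, space, cfg)
        assert np.array_equal(a.best_position, b.best_position)
        assert a.best_fitness == b.best_fitness
        assert np.array_equal(a.convergence, b.convergence)
        assert a.n_evals == b.n_evals

    def test_single_iteration_budget_performs_one_sweep(self):
        res = hho.hho_optimize(
            sphere, UNIT_SQUARE, hho.HhoConfig(n_hawks=6, max_iter=1, seed=0)
        )
        assert res.convergence.size == 1
        assert res.n_evals >= 6

    def test_objective_exception_carries_iteration_context(self):
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if calls["n"] > 8:
                raise RuntimeError("boom")
            return sphere(x)

        with pytest.raises(hho.ObjectiveError, match="iteration|dive"):
            hho.hho_optimize(flaky, UNIT_SQUARE, hho.HhoConfig(n_hawks=5, max_iter=10, seed=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            hho.HhoConfig(n_hawks=1)
        with pytest.raises(ValueError):
            hho.HhoConfig(max_iter=0)
        with pytest.raises(ValueError):
            hho.HhoConfig(beta=2.5)
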