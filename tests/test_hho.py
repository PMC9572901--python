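import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hhoselect.hho import (
    HHOParams,
    HawkPopulation,
    escape_energy,
    exploration_step,
    hard_siege_dives,
    hard_siege_step,
    hho_minimize,
    initialize_population,
    jump_strength,
    levy_step,
    mean_position,
    soft_siege_dives,
    soft_siege_step,
)

PARAMS_1D = HHOParams(dim=1)


def sphere(x):
    return float(np.sum(x**2))


class TestScalarUpdates:
    @pytest.mark.parametrize(
        "e0,t,mi,expected",
        [(0.5, 0, 100, 1.0), (-0.8, 100, 100, 0.0), (0.5, 50, 100, 0.5)],
    )
    def test_escape_energy(self, e0, t, mi, expected):
        assert escape_energy(e0, t, mi) == pytest.approx(expected)

    def test_escape_energy_rejects_t_beyond_horizon(self):
        with pytest.raises(ValueError):
            escape_energy(0.5, 101, 100)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-1, 1), st.integers(0, 100))
    def test_energy_envelope(self, e0, t):
        e = escape_energy(e0, t, 100)
        assert abs(e) <= 2 * abs(e0) * (1 - t / 100) + 1e-12
        assert abs(e) <= 2 * abs(e0) + 1e-12

    @pytest.mark.parametrize("r,expected", [(0.5, 1.0), (1 - 1e-12, 0.0), (1e-12, 2.0)])
    def test_jump_strength(self, r, expected):
        assert jump_strength(r) == pytest.approx(expected, abs=1e-9)


class TestMeanPosition:
    def test_two_hawks(self):
        pop = HawkPopulation(
            positions=np.array([[0.0, 0.0], [1.0, 1.0]]),
            fitnesses=np.zeros(2), rabbit_position=np.zeros(2), rabbit_fitness=0.0,
        )
        np.testing.assert_allclose(mean_position(pop), [0.5, 0.5])

    def test_matches_independent_summation(self):
        rng = np.random.default_rng(0)
        rows = rng.uniform(size=(10, 4))
        pop = HawkPopulation(
            positions=rows, fitnesses=np.zeros(10),
            rabbit_position=rows[0], rabbit_fitness=0.0,
        )
        expected = sum(rows[i] for i in range(10)) / 10  # brute-force oracle
        np.testing.assert_allclose(mean_position(pop), expected)


class TestExplorationStep:
    def test_r1_zero_returns_random_hawk(self):
        x = np.array([0.3])
        out = exploration_step(
            x, np.array([0.8]), np.array([0.9]), np.array([0.4]),
            q=0.9, r1=0.0, r2=0.7, r3=0.1, r4=0.2, params=PARAMS_1D,
        )
        np.testing.assert_allclose(out, [0.8])

    def test_rabbit_equals_mean_with_r3_zero(self):
        v = np.array([0.5, 0.5])
        out = exploration_step(
            v, v, v, v, q=0.1, r1=0.3, r2=0.3, r3=0.0, r4=0.9,
            params=HHOParams(dim=2),
        )
        np.testing.assert_allclose(out, [0.0, 0.0])

    def test_hand_evaluated_perch_branch(self):
        # 0.8 - 0.5*|0.8 - 2*0.5*0.4| = 0.6
        out = exploration_step(
            np.array([0.4]), np.array([0.8]), np.array([0.1]), np.array([0.2]),
            q=0.9, r1=0.5, r2=0.5, r3=0.1, r4=0.1, params=PARAMS_1D,
        )
        np.testing.assert_allclose(out, [0.6])


class TestSiegeSteps:
    def test_soft_siege_with_zero_energy_is_delta(self):
        x, rabbit = np.array([0.2, 0.8]), np.array([0.6, 0.9])
        out = soft_siege_step(x, rabbit, e=0.0, j=1.3, params=HHOParams(dim=2))
        np.testing.assert_allclose(out, rabbit - x)  # delta lies inside the box

    def test_soft_siege_hand_value_clipped(self):
        # (0-1) - 0.5*|0-1| = -1.5, clipped into [0, 1]
        out = soft_siege_step(
            np.array([1.0]), np.array([0.0]), e=0.5, j=1.0, params=PARAMS_1D
        )
        np.testing.assert_allclose(out, [0.0])

    def test_soft_siege_at_rabbit_symbolic(self):
        rabbit = np.array([0.6])
        for j in (0.3, 1.0, 1.7):
            out = soft_siege_step(rabbit, rabbit, e=0.6, j=j, params=PARAMS_1D)
            expected = np.clip(-0.6 * abs(j - 1) * rabbit, 0, 1)
            np.testing.assert_allclose(out, expected)

    def test_hard_siege_identity_cases(self):
        x, rabbit = np.array([0.6]), np.array([0.4])
        np.testing.assert_allclose(
            hard_siege_step(x, rabbit, e=0.0, params=PARAMS_1D), x
        )
        np.testing.assert_allclose(
            hard_siege_step(rabbit, rabbit, e=0.3, params=PARAMS_1D), rabbit
        )

    def test_hard_siege_hand_value(self):
        out = hard_siege_step(
            np.array([0.6]), np.array([0.4]), e=0.2, params=PARAMS_1D
        )
        np.testing.assert_allclose(out, [0.56])  # 0.6 - 0.2*|0.4-0.6|


class TestLevyStep:
    def test_length_and_determinism(self):
        a = levy_step(7, np.random.default_rng(5))
        b = levy_step(7, np.random.default_rng(5))
        assert a.shape == (7,)
        np.testing.assert_array_equal(a, b)

    def test_heavy_tail(self):
        rng = np.random.default_rng(11)
        steps = np.abs(np.concatenate([levy_step(1000, rng) for _ in range(100)]))
        assert np.quantile(steps, 0.999) > 10 * np.median(steps)


class TestRapidDives:
    def test_accepts_first_dive_with_minimal_evaluations(self):
        calls = []

        def f(v):
            calls.append(v.copy())
            return sphere(v)

        x = np.array([0.9])
        out = soft_siege_dives(
            x, np.array([0.1]), e=0.6, j=1.0, fitness=f,
            params=PARAMS_1D, rng=np.random.default_rng(0), f_x=sphere(x),
        )
        # k = 0.1 - 0.6*|0.1 - 0.9| = -0.38 -> clipped to 0, beats x
        np.testing.assert_allclose(out, [0.0])
        assert len(calls) == 1  # z never evaluated when k wins

    def test_fall_through_keeps_hawk(self):
        x = np.array([0.05])  # already near the sphere optimum
        out = soft_siege_dives(
            x, np.array([0.5]), e=-0.9, j=1.9, fitness=sphere,
            params=PARAMS_1D, rng=np.random.default_rng(3), f_x=sphere(x),
        )
        if not np.array_equal(out, x):
            assert sphere(out) < sphere(x)

    def test_hard_dive_hand_value(self):
        # k = 0.5 - 0.4*|0.5 - 0.3| = 0.42; fitness ranks k best so it's accepted
        target = 0.42

        def f(v):
            return abs(float(v[0]) - target)

        x = np.array([0.9])
        out = hard_siege_dives(
            x, np.array([0.5]), np.array([0.3]), e=0.4, j=1.0, fitness=f,
            params=PARAMS_1D, rng=np.random.default_rng(0), f_x=f(x),
        )
        np.testing.assert_allclose(out, [target])

    def test_hard_dive_zero_energy_jumps_to_rabbit(self):
        rabbit = np.array([0.2])
        out = hard_siege_dives(
            np.array([0.9]), rabbit, np.array([0.5]), e=0.0, j=1.2,
            fitness=sphere, params=PARAMS_1D,
            rng=np.random.default_rng(0), f_x=sphere(np.array([0.9])),
        )
        np.testing.assert_allclose(out, rabbit)

    def test_greedy_acceptance_never_worsens(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            x = rng.uniform(size=1)
            rabbit = np.array([0.0])
            e = rng.uniform(-1, 1)
            out = soft_siege_dives(
                x, rabbit, e=e, j=jump_strength(rng.uniform()),
                fitness=sphere, params=PARAMS_1D, rng=rng, f_x=sphere(x),
            )
            assert sphere(out) <= sphere(x) + 1e-12


class TestInitialization:
    def test_shapes_and_box(self):
        pop = initialize_population(HHOParams(dim=5, n_hawks=10, seed=0), sphere)
        assert pop.positions.shape == (10, 5)
        assert np.all((pop.positions >= 0) & (pop.positions <= 1))

    def test_constant_fitness(self):
        pop = initialize_population(
            HHOParams(dim=3, n_hawks=4, seed=1), lambda x: 7.5
        )
        assert pop.rabbit_fitness == 7.5

    def test_rabbit_is_bruteforce_argmin(self):
        c = np.array([0.3, 0.7, 0.5])
        f = lambda x: float(np.sum((x - c) ** 2))
        pop = initialize_population(HHOParams(dim=3, n_hawks=50, seed=2), f)
        best_row = min(range(50), key=lambda i: f(pop.positions[i]))
        np.testing.assert_array_equal(pop.rabbit_position, pop.positions[best_row])

    def test_nan_fitness_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            initialize_population(HHOParams(dim=2, seed=0), lambda x: float("nan"))


class TestMinimize:
    def test_elitism_and_improvement_on_sphere(self):
        res = hho_minimize(sphere, HHOParams(dim=5, n_hawks=10, max_iter=100, seed=0))
        assert res.best_fitness < res.history[0] or res.history[0] == res.best_fitness
        assert np.all(np.diff(res.history) <= 0)
        assert res.best_fitness < 1e-3

    def test_single_iteration(self):
        res = hho_minimize(sphere, HHOParams(dim=3, seed=0, max_iter=1))
        assert res.history.shape == (1,)

    def test_box_containment_observed_by_objective(self):
        params = HHOParams(dim=4, max_iter=30, seed=3, lb=0.2, ub=0.8)

        def guarded(x):
            assert np.all(x >= 0.2 - 1e-12) and np.all(x <= 0.8 + 1e-12)
            return sphere(x)

        hho_minimize(guarded, params)

    def test_full_determinism_under_seed(self):
        p = HHOParams(dim=4, max_iter=40, seed=123)
        r1 = hho_minimize(sphere, p)
        r2 = hho_minimize(sphere, p)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)
        np.testing.assert_array_equal(r1.history, r2.history)
        assert r1.n_evaluations == r2.n_evaluations

    def test_converges_to_1d_target(self):
        f = lambda x: abs(float(x[0]) - 0.7)
        hits = sum(
            abs(hho_minimize(f, HHOParams(dim=1, seed=s)).best_position[0] - 0.7) < 0.05
            for s in range(20)
        )
        assert hits >= 18

    def test_callback_reports_each_iteration(self):
        log = []
        hho_minimize(
            sphere, HHOParams(dim=2, max_iter=7, seed=0),
            callback=lambda t, fit, ne: log.append((t, fit)),
        )
        assert [t for t, _ in log] == list(range(1, 8))
        assert all(b[1] <= a[1] for a, b in zip(log, log[1:]))


@pytest.mark.parametrize(
    "kwargs", [dict(dim=0), dict(dim=2, n_hawks=1), dict(dim=2, max_iter=0),
               dict(dim=2, lb=1.0, ub=0.0)]
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        HHOParams(**kwargs)
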