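"""Unit and property tests for the continuous BER optimizer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from biruni import (
    BERSettings,
    ObjectiveSpec,
    exploit_around_leader,
    exploit_toward_leader,
    exploration_step,
    initialize_population,
    make_benchmark,
    mutate,
    run,
    run_random_search,
    sample_r,
    step,
    update_group_sizes,
)


def sphere_spec(d=5, lo=-5.0, hi=5.0):
    return make_benchmark("sphere", d).to_objective() if (lo, hi) == (-100.0, 100.0) else ObjectiveSpec(
        dimension=d,
        lower_bounds=np.full(d, lo),
        upper_bounds=np.full(d, hi),
        evaluate=lambda x: float(np.sum(x * x)),
        name="sphere",
    )


# ---------------------------------------------------------------------------
# Elementary update rules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "h, x, expected",
    [
        (1.7, 90.0, 0.0),       # cos 90 = 0 -> zero numerator
        (1.0, 180.0, -0.5),     # cos 180 = -1 -> -1/2
        (1.0, 60.0, 1.0),       # 0.5 / (1 - 0.5)
    ],
)
def test_sample_r_closed_forms(h, x, expected):
    assert sample_r(h, x) == pytest.approx(expected, abs=1e-12)


def test_sample_r_cap_and_domain():
    assert sample_r(2.0, 0.5, r_cap=10.0) == 10.0  # near-singular angle capped
    with pytest.raises(ValueError):
        sample_r(1.0, 0.0)
    with pytest.raises(ValueError):
        sample_r(1.0, 180.5)


def test_exploration_step_null_move_and_fixed_point():
    s = np.array([2.0, -3.0, 0.5])
    # 2*r2 - 1 = 0 leaves the position unchanged
    assert np.allclose(exploration_step(s, np.full(3, 0.7), np.full(3, 0.5)), s)
    # S = 1 makes D vanish
    ones = np.ones(4)
    assert np.allclose(exploration_step(ones, np.full(4, 0.3), np.full(4, 0.9)), ones)


def test_exploration_step_arithmetic_and_shapes():
    out = exploration_step(np.array([3.0]), np.array([0.5]), np.array([1.0]))
    assert out == pytest.approx([4.0])  # D = 0.5*(3-1) = 1; 3 + 1*1
    with pytest.raises(ValueError):
        exploration_step(np.ones(3), np.ones(2), np.ones(3))


def test_exploit_toward_leader_limits():
    s, lead = np.array([1.0, 2.0]), np.array([5.0, -1.0])
    assert np.allclose(exploit_toward_leader(s, lead, 1.0, np.ones(2)), lead)
    assert np.allclose(exploit_toward_leader(s, lead, 0.0, np.ones(2)), 0.0)
    assert exploit_toward_leader(
        np.array([0.0]), np.array([2.0]), 1.0, np.array([0.5])
    ) == pytest.approx([1.0])


def test_exploit_around_leader_schedule():
    lead = np.array([1.0, -2.0])
    assert np.allclose(exploit_around_leader(lead, 0.5, 0.0, 0, 10), 0.5 * lead)
    # t = N with z = 0 gives offset k = 2
    assert np.allclose(exploit_around_leader(lead, 1.0, 0.0, 10, 10), lead + 2.0)
    assert exploit_around_leader(
        np.array([1.0]), 1.0, 0.5, 5, 10
    ) == pytest.approx([2.0])  # k = 0.5 + 2*25/100 = 1
    with pytest.raises(ValueError):
        exploit_around_leader(lead, 1.0, 0.5, 0, 0)


@pytest.mark.parametrize(
    "k, z, h, x, expected",
    [
        (3.0, 0.0, 1.0, 90.0, 0.0),
        (1.0, 1.0, 1.0, 90.0, 1.0),
        (2.0, 0.5, 1.0, 60.0, -0.5),  # 2*0.25 - 1.0
    ],
)
def test_mutate_closed_forms(k, z, h, x, expected):
    assert mutate(k, z, h, x) == pytest.approx(expected, abs=1e-12)


def test_group_size_schedule():
    settings = BERSettings(population_size=10, iterations=100)
    assert update_group_sizes(0, settings) == (3, 7)
    assert update_group_sizes(100, settings) == (7, 3)
    assert update_group_sizes(50, settings) == (5, 5)


@given(
    n=st.integers(min_value=2, max_value=60),
    t=st.integers(min_value=0, max_value=40),
)
@hyp_settings(deadline=None, max_examples=60)
def test_group_conservation_and_floor(n, t):
    settings = BERSettings(population_size=n, iterations=40)
    n_ex, n_ep = update_group_sizes(t, settings)
    assert n_ex + n_ep == n
    assert n_ex >= 1 and n_ep >= 1


# ---------------------------------------------------------------------------
# Population initialization
# ---------------------------------------------------------------------------

def test_initialize_degenerate_bounds():
    spec = ObjectiveSpec(
        dimension=2,
        lower_bounds=np.array([2.0, 2.0]),
        upper_bounds=np.array([2.0, 2.0]),
        evaluate=lambda x: float(np.sum(x)),
    )
    state = initialize_population(spec, BERSettings(population_size=6, seed=3))
    for agent in state.agents:
        assert np.allclose(agent.position, [2.0, 2.0])


def test_initialize_roles_and_leader():
    spec = sphere_spec(d=3, lo=0.0, hi=1.0)
    state = initialize_population(spec, BERSettings(population_size=10, seed=0))
    roles = [a.role for a in state.agents]
    assert roles.count("exploitation") == 3
    assert roles.count("exploration") == 7
    assert state.leader.fitness == min(a.fitness for a in state.agents)
    assert state.evaluations == 10


def test_initialize_matches_independent_seeded_redraw():
    """Positions reproduce an independent re-draw of the documented protocol:
    one uniform block of shape (n, d) over [lower, upper) from the seed."""
    spec = sphere_spec(d=5, lo=0.0, hi=1.0)
    state = initialize_population(spec, BERSettings(population_size=4, seed=123))
    expected = np.random.default_rng(123).uniform(0.0, 1.0, size=(4, 5))
    got = np.stack([a.position for a in state.agents])
    assert np.array_equal(got, expected)


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        ObjectiveSpec(dimension=0, lower_bounds=np.array([]),
                      upper_bounds=np.array([]), evaluate=lambda x: 0.0)
    with pytest.raises(ValueError):
        ObjectiveSpec(dimension=1, lower_bounds=np.array([1.0]),
                      upper_bounds=np.array([0.0]), evaluate=lambda x: 0.0)


# ---------------------------------------------------------------------------
# Step and run dynamics
# ---------------------------------------------------------------------------

def test_step_elitism_and_flat_landscape():
    spec = sphere_spec(d=3, lo=-5.0, hi=5.0)
    settings = BERSettings(population_size=8, iterations=20, seed=7)
    state = initialize_population(spec, settings)
    for _ in range(20):
        before = state.leader.fitness
        step(state, spec, settings)
        assert state.leader.fitness <= before

    flat = ObjectiveSpec(dimension=2, lower_bounds=np.full(2, -1.0),
                         upper_bounds=np.full(2, 1.0),
                         evaluate=lambda x: 5.0, name="flat")
    state = initialize_population(flat, settings)
    for _ in range(10):
        step(state, flat, settings)
    assert state.leader.fitness == 5.0


def test_single_exploration_step_hand_trace():
    """A 1-agent population explores; the move is a straight transcription of
    D = r1*(S-1), S' = S + D*(2*r2-1) with the same generator draws."""
    spec = sphere_spec(d=1, lo=-5.0, hi=5.0)
    settings = BERSettings(population_size=1, iterations=10, seed=0)
    state = initialize_population(spec, settings)
    assert state.agents[0].role == "exploration"
    s0 = state.agents[0].position.copy()

    oracle_rng = np.random.default_rng(0)
    oracle_rng.uniform(-5.0, 5.0, size=(1, 1))       # replay initial draw
    r1 = oracle_rng.uniform(0.0, 1.0, size=1)
    r2 = oracle_rng.uniform(0.0, 1.0, size=1)
    expected = np.clip(s0 + r1 * (s0 - 1.0) * (2.0 * r2 - 1.0), -5.0, 5.0)

    step(state, spec, settings)
    assert np.allclose(state.agents[0].position, expected)


def test_non_finite_fitness_warns_and_is_inf():
    spec = ObjectiveSpec(dimension=1, lower_bounds=np.array([-1.0]),
                         upper_bounds=np.array([1.0]),
                         evaluate=lambda x: float("nan"), name="bad")
    with pytest.warns(RuntimeWarning):
        state = initialize_population(spec, BERSettings(population_size=2, seed=0))
    assert all(math.isinf(a.fitness) for a in state.agents)


def test_run_zero_iterations_returns_initial_best():
    spec = sphere_spec(d=4, lo=-5.0, hi=5.0)
    settings = BERSettings(population_size=6, iterations=0, seed=5)
    result = run(spec, settings)
    state = initialize_population(spec, settings)
    assert result.best_fitness == state.leader.fitness
    assert result.trajectory == [state.leader.fitness]


def test_run_feasibility_budget_and_monotonicity():
    spec = make_benchmark("schwefel_2_22", 6).to_objective()
    settings = BERSettings(population_size=10, iterations=30, seed=2)
    result = run(spec, settings)
    assert np.all(result.best_position >= spec.lower_bounds - 1e-12)
    assert np.all(result.best_position <= spec.upper_bounds + 1e-12)
    assert all(a >= b for a, b in zip(result.trajectory, result.trajectory[1:]))
    assert result.trajectory[-1] == result.best_fitness
    n, big_n = settings.population_size, settings.iterations
    max_mutations = n * big_n // settings.stagnation_window
    assert result.evaluations <= n * (big_n + 1) + max_mutations


@given(seed=st.integers(min_value=0, max_value=10_000))
@hyp_settings(deadline=None, max_examples=15)
def test_elitism_property_across_seeds(seed):
    spec = make_benchmark("sum_squares", 4).to_objective()
    result = run(spec, BERSettings(population_size=6, iterations=15, seed=seed))
    assert all(a >= b for a, b in zip(result.trajectory, result.trajectory[1:]))


def test_beats_random_search_on_sphere():
    """Median final best over 10 seeds must undercut equal-budget random search."""
    spec = make_benchmark("sphere", 10).to_objective()
    ber_best, rs_best = [], []
    for seed in range(10):
        res = run(spec, BERSettings(population_size=15, iterations=50, seed=seed))
        ber_best.append(res.best_fitness)
        rs_best.append(run_random_search(spec, res.evaluations, seed=seed).best_fitness)
    assert np.median(ber_best) < np.median(rs_best)
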