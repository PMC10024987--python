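"""Simplex conservation, fixed points and stationary distributions."""

import numpy as np
import pytest

from thresholdpgg import make_treatment
from thresholdpgg.dynamics import (DynamicsParams, initial_condition,
                                   introspection_stationary,
                                   introspection_transition_matrix,
                                   modal_outcome, run_best_response,
                                   run_birth_death, run_replicator,
                                   stationary_distribution,
                                   trajectory_to_frame)
from thresholdpgg.equilibrium import enumerate_pure_nash, is_nash
from thresholdpgg.game import payoff_matrices


def point_mass(cfg, profile):
    x = np.zeros(cfg.e1 + 1)
    y = np.zeros(cfg.e2 + 1)
    x[profile[0]] = 1.0
    y[profile[1]] = 1.0
    return x, y


def assert_on_simplex(traj):
    for x, y in traj.states:
        for v in (x, y):
            assert abs(v.sum() - 1.0) < 1e-9
            assert np.all(v >= -1e-9)


# -- initial conditions --------------------------------------------------------


def test_uniform_init(full_equality):
    x, y = initial_condition(full_equality, "uniform")
    assert x.shape == (13,) and y.shape == (13,)
    assert np.allclose(x, 1 / 13) and np.allclose(y, 1 / 13)


def test_random_init_seeded(full_equality):
    a = initial_condition(full_equality, "random", seed=11)
    b = initial_condition(full_equality, "random", seed=11)
    c = initial_condition(full_equality, "random", seed=12)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    assert not np.array_equal(a[0], c[0])
    for v in a:
        assert abs(v.sum() - 1.0) < 1e-9


def test_empirical_init_normalizes_and_validates(full_equality):
    w = np.zeros(13)
    w[6] = 2.0   # unnormalized point mass at half endowment
    x, y = initial_condition(full_equality, "empirical", source=(w, w))
    assert x[6] == 1.0 and y[6] == 1.0
    with pytest.raises(ValueError, match="requires a source"):
        initial_condition(full_equality, "empirical")
    with pytest.raises(ValueError, match="length"):
        initial_condition(full_equality, "empirical", source=(w[:5], w))


# -- replicator / best response ------------------------------------------------


def test_strict_nash_point_mass_is_stationary(treatment):
    """Point masses at strict pure equilibria are fixed points of both the
    replicator and the best-response dynamic."""
    strict = [eq.profile for eq in enumerate_pure_nash(treatment).equilibria
              if eq.strictness == "strict"]
    assert strict, "every default treatment has a strict equilibrium"
    short = DynamicsParams(time_horizon=5.0)
    for profile in strict:
        init = point_mass(treatment, profile)
        for runner in (run_replicator, run_best_response):
            traj = runner(treatment, init, short)
            x, y = traj.final_state
            assert np.abs(x - init[0]).max() < 1e-12
            assert np.abs(y - init[1]).max() < 1e-12


def test_replicator_uniform_limit_is_nash(treatment):
    traj = run_replicator(treatment, initial_condition(treatment, "uniform"),
                          DynamicsParams())
    assert traj.converged
    assert is_nash(treatment, traj.limit_profile)[0]
    assert_on_simplex(traj)


def test_replicator_moderate_productivity_role2_defects():
    """From uniform initial conditions the less productive player ends up
    contributing nothing under moderate productivity inequality."""
    cfg = make_treatment("moderate_productivity")
    traj = run_replicator(cfg, initial_condition(cfg, "uniform"), DynamicsParams())
    _, y = traj.final_state
    assert y[1:].sum() < 1e-4
    assert modal_outcome(traj) == (6, 0)


def test_replicator_uniform_limits_by_treatment():
    """From uniform initial conditions the replicator selects mutual
    defection whenever (0, 0) is an equilibrium, and otherwise a cooperative
    equilibrium where the less productive player contributes at most one
    coin: (6, 0) under moderate and (5, 1) under strong productivity
    inequality."""
    expected = {
        "full_equality": (0, 0),
        "moderate_endowment": (0, 0),
        "strong_endowment": (0, 0),
        "moderate_productivity": (6, 0),
        "strong_productivity": (5, 1),
    }
    for name, limit in expected.items():
        cfg = make_treatment(name)
        traj = run_replicator(cfg, initial_condition(cfg, "uniform"),
                              DynamicsParams())
        assert traj.converged and traj.limit_profile == limit


def test_best_response_full_jump(full_equality):
    """With step size 1 the state jumps straight onto the best-response
    mixture: against a co-player at half endowment the unique reply is 6."""
    init = point_mass(full_equality, (0, 6))
    params = DynamicsParams(step_size=1.0, time_horizon=5)
    traj = run_best_response(full_equality, init, params)
    x1 = traj.states[1][0]
    assert x1[6] == 1.0
    assert_on_simplex(traj)


def test_best_response_simplex_from_random_init(treatment):
    init = initial_condition(treatment, "random", seed=3)
    traj = run_best_response(treatment, init, DynamicsParams(time_horizon=500))
    assert_on_simplex(traj)


# -- birth-death ---------------------------------------------------------------


def test_birth_death_seeded_reproducible(full_equality):
    init = initial_condition(full_equality, "uniform")
    params = DynamicsParams(seed=9, time_horizon=3000)
    t1 = run_birth_death(full_equality, init, params)
    t2 = run_birth_death(full_equality, init, params)
    assert np.array_equal(t1.times, t2.times)
    for (a1, a2), (b1, b2) in zip(t1.states, t2.states):
        assert np.array_equal(a1, b1) and np.array_equal(a2, b2)
    assert_on_simplex(t1)


def test_birth_death_requires_seed(full_equality):
    init = initial_condition(full_equality, "uniform")
    with pytest.raises(ValueError, match="seed"):
        run_birth_death(full_equality, init, DynamicsParams(seed=None))


def test_birth_death_mu1_approaches_uniform(full_equality):
    """With mutation probability 1 every update randomizes, so long-run
    frequencies approach the uniform distribution."""
    init = point_mass(full_equality, (0, 0))
    params = DynamicsParams(seed=1, mutation_rate=1.0, time_horizon=60000)
    traj = run_birth_death(full_equality, init, params)
    late = traj.states[len(traj.states) // 2:]
    mean_x = np.mean([s[0] for s in late], axis=0)
    mean_y = np.mean([s[1] for s in late], axis=0)
    assert np.abs(mean_x - 1 / 13).max() < 0.05
    assert np.abs(mean_y - 1 / 13).max() < 0.05


def test_birth_death_mu0_retains_strict_nash(treatment):
    """Without mutation, a monomorphic population at a strict equilibrium
    never moves: imitation between identical strategies is a no-op."""
    erc = treatment.half_profile
    init = point_mass(treatment, erc)
    params = DynamicsParams(seed=4, mutation_rate=0.0, time_horizon=10000)
    traj = run_birth_death(treatment, init, params)
    x, y = traj.final_state
    assert x[erc[0]] == 1.0 and y[erc[1]] == 1.0


# -- introspection -------------------------------------------------------------


def test_introspection_transition_matrix_stochastic(treatment):
    A, B = payoff_matrices(treatment)
    T = introspection_transition_matrix(A, B, beta=1.0)
    assert np.allclose(T.sum(axis=1), 1.0, atol=1e-15)
    assert np.all(T >= 0)


def test_introspection_beta0_uniform(treatment):
    pi = introspection_stationary(treatment, DynamicsParams(selection_strength=0.0))
    n = (treatment.e1 + 1) * (treatment.e2 + 1)
    assert np.allclose(pi, 1.0 / n, atol=1e-12)


def test_introspection_stationarity_residual(treatment):
    A, B = payoff_matrices(treatment)
    T = introspection_transition_matrix(A, B, beta=1.0)
    pi = stationary_distribution(T)
    assert np.abs(pi @ T - pi).max() < 1e-10
    assert abs(pi.sum() - 1.0) < 1e-12


def test_introspection_exact_vs_simulated(full_equality):
    exact = introspection_stationary(full_equality, DynamicsParams())
    sim = introspection_stationary(
        full_equality, DynamicsParams(time_horizon=1e6, seed=13), mode="simulated")
    tv = 0.5 * np.abs(exact - sim).sum()
    assert tv < 0.02


def test_introspection_simulated_requires_seed(full_equality):
    with pytest.raises(ValueError, match="seed"):
        introspection_stationary(full_equality, DynamicsParams(seed=None),
                                 mode="simulated")


# -- ERC retention (empirical-initial-condition mechanism) ---------------------


def test_erc_point_mass_retained_by_all_dynamics(treatment):
    """Starting exactly at the equal-relative-contributions equilibrium, the
    deterministic dynamics stay put and the mutation-free stochastic ones
    keep the whole population there."""
    erc = treatment.half_profile
    init = point_mass(treatment, erc)
    for runner in (run_replicator, run_best_response):
        traj = runner(treatment, init, DynamicsParams(time_horizon=10))
        assert modal_outcome(traj) == erc
    traj = run_birth_death(treatment, init,
                           DynamicsParams(seed=2, mutation_rate=0.0,
                                          time_horizon=5000))
    assert modal_outcome(traj) == erc


# -- misc ----------------------------------------------------------------------


def test_modal_outcome_tie_breaks_lexicographically(full_equality):
    from thresholdpgg.dynamics import Trajectory
    x = np.zeros(13)
    y = np.zeros(13)
    x[[3, 7]] = 0.5
    y[[2, 5]] = 0.5
    traj = Trajectory(np.array([0.0]), [(x, y)], converged=False)
    assert modal_outcome(traj) == (3, 2)
    with pytest.raises(ValueError, match="empty"):
        modal_outcome(Trajectory(np.array([]), [], converged=False))


def test_trajectory_frame_schema(full_equality):
    traj = run_replicator(full_equality, initial_condition(full_equality, "uniform"),
                          DynamicsParams(time_horizon=1.0))
    frame = trajectory_to_frame(traj)
    assert list(frame.columns) == ["time", "role", "contribution", "weight"]
    sums = frame.groupby(["time", "role"])["weight"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)
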