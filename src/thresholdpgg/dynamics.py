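"""Evolutionary and learning dynamics over the one-shot strategy space.

Each player role has the finite strategy set {0, ..., e_role} (all pure
contribution levels).  The population state is a pair of mixed strategies
(x, y), one probability vector per role.  Four dynamics are provided:

``run_replicator``
    Deterministic two-population replicator equation, integrated with a
    fixed-step fourth-order Runge-Kutta scheme.  A strategy's frequency in
    one role grows in proportion to its payoff advantage against the other
    role's current mixture, relative to the role's mean payoff.

``run_best_response``
    Discrete-time smoothed best-response dynamic: each step, every role's
    state moves a step-size fraction toward the uniform mixture over its
    current pure best responses (ties split equally).

``run_birth_death``
    Stochastic pairwise-comparison (Moran-like) process in two finite
    sub-populations of size N, one per role.  Each step a focal and a model
    individual of one role are drawn; the focal imitates the model with the
    Fermi probability 1 / (1 + exp(-beta * (pi_model - pi_focal))), or
    mutates to a uniformly random strategy with probability mu.

``introspection_stationary``
    A single pair of players who repeatedly compare their current
    contribution with a randomly drawn alternative and switch with the
    Fermi probability.  This is a finite Markov chain over joint profiles;
    the exact mode returns its unique stationary distribution, the
    simulated mode a seeded long-run occupancy estimate.

All updates act on payoff matrices only, so the same machinery drives the
repeated-game strategy families (see :mod:`thresholdpgg.repeated`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .game import GameConfig, payoff_matrices

__all__ = [
    "DynamicsParams",
    "Trajectory",
    "initial_condition",
    "run_replicator",
    "run_best_response",
    "run_birth_death",
    "introspection_stationary",
    "introspection_transition_matrix",
    "stationary_distribution",
    "modal_outcome",
    "trajectory_to_frame",
]

_SIMPLEX_TOL = 1e-9


@dataclass
class DynamicsParams:
    """Shared knobs of the four dynamics.

    ``selection_strength`` (beta) scales payoff differences inside the Fermi
    function for the stochastic dynamics; ``mutation_rate`` (mu) is the
    per-update probability of adopting a uniformly random strategy in the
    birth-death process; ``population_size`` (N) is the number of
    individuals per role sub-population.  ``time_horizon`` is continuous
    time for the replicator (integrated with RK4 steps of ``step_size``)
    and the number of discrete updates for the other dynamics.
    """

    selection_strength: float = 1.0
    mutation_rate: float = 0.01
    population_size: int = 100
    time_horizon: float = 2000.0
    step_size: float = 0.01
    seed: int | None = None
    convergence_tol: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.step_size <= 0 or self.time_horizon <= 0 or self.convergence_tol <= 0:
            raise ValueError("step_size, time_horizon, convergence_tol must be positive")


@dataclass
class Trajectory:
    """Recorded time evolution of the two roles' mixed strategies."""

    times: np.ndarray
    states: list[tuple[np.ndarray, np.ndarray]]
    converged: bool
    limit_profile: tuple[int, int] | None = None

    @property
    def final_state(self) -> tuple[np.ndarray, np.ndarray]:
        return self.states[-1]


def _check_simplex(v: np.ndarray, label: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(v < -_SIMPLEX_TOL) or abs(v.sum() - 1.0) > 1e-6:
        raise ValueError(f"{label} is not a probability vector (sum {v.sum()})")
    return np.clip(v, 0.0, None) / v.sum()


def initial_condition(config: GameConfig, kind: str = "uniform",
                      source: tuple[Sequence[float], Sequence[float]] | None = None,
                      seed: int | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Initial mixed-strategy pair for the dynamics.

    ``uniform`` puts equal weight on every contribution level; ``random``
    draws each role's state from a flat Dirichlet under ``seed``;
    ``empirical`` normalizes a caller-supplied weight vector per role
    (typically a first-round contribution histogram from
    :func:`thresholdpgg.experiment.first_round_distribution`).
    """
    sizes = (config.e1 + 1, config.e2 + 1)
    if kind == "uniform":
        return tuple(np.full(n, 1.0 / n) for n in sizes)
    if kind == "random":
        rng = np.random.default_rng(seed)
        return tuple(rng.dirichlet(np.ones(n)) for n in sizes)
    if kind == "empirical":
        if source is None:
            raise ValueError("empirical initial condition requires a source distribution")
        out = []
        for role, (weights, n) in enumerate(zip(source, sizes), start=1):
            w = np.asarray(weights, dtype=float)
            if w.shape != (n,):
                raise ValueError(
                    f"role {role} source has length {w.size}, expected {n}")
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError(f"role {role} source must be non-negative, non-zero")
            out.append(w / w.sum())
        return tuple(out)
    raise ValueError(f"unknown initial-condition kind {kind!r}")


def _modal_profile(x: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    joint = np.outer(x, y)
    best = joint.max()
    ties = np.argwhere(joint >= best - 1e-15)
    c1, c2 = min(map(tuple, ties))
    return int(c1), int(c2)


def modal_outcome(trajectory: Trajectory) -> tuple[int, int]:
    """Pure profile maximizing the product of final per-role weights.

    Ties resolve toward the lexicographically smallest (c1, c2).
    """
    if not trajectory.states:
        raise ValueError("empty trajectory")
    return _modal_profile(*trajectory.final_state)


# -- replicator ----------------------------------------------------------------


def _replicator_rhs(A: np.ndarray, B: np.ndarray, x: np.ndarray, y: np.ndarray):
    fx = A @ y
    fy = B.T @ x
    return x * (fx - x @ fx), y * (fy - y @ fy)


def _run_replicator(A: np.ndarray, B: np.ndarray,
                    x: np.ndarray, y: np.ndarray,
                    params: DynamicsParams) -> Trajectory:
    dt = params.step_size
    n_steps = int(round(params.time_horizon / dt))
    record_every = max(1, n_steps // 2000)
    times, states = [0.0], [(x.copy(), y.copy())]
    converged = False
    for step in range(1, n_steps + 1):
        k1x, k1y = _replicator_rhs(A, B, x, y)
        k2x, k2y = _replicator_rhs(A, B, x + 0.5 * dt * k1x, y + 0.5 * dt * k1y)
        k3x, k3y = _replicator_rhs(A, B, x + 0.5 * dt * k2x, y + 0.5 * dt * k2y)
        k4x, k4y = _replicator_rhs(A, B, x + dt * k3x, y + dt * k3y)
        nx = x + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        ny = y + dt / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
        if not (np.all(np.isfinite(nx)) and np.all(np.isfinite(ny))):
            raise RuntimeError(f"replicator integration diverged at t={step * dt}")
        # RK4 drift off the simplex is tiny; renormalize, abort if it is not
        for v in (nx, ny):
            if abs(v.sum() - 1.0) > 1e-6:
                raise RuntimeError("replicator state left the simplex beyond tolerance")
        nx = np.clip(nx, 0.0, None); nx /= nx.sum()
        ny = np.clip(ny, 0.0, None); ny /= ny.sum()
        delta = max(np.abs(nx - x).max(), np.abs(ny - y).max())
        x, y = nx, ny
        if step % record_every == 0:
            times.append(step * dt)
            states.append((x.copy(), y.copy()))
        if delta < params.convergence_tol:
            converged = True
            break
    if times[-1] != step * dt:
        times.append(step * dt)
        states.append((x.copy(), y.copy()))
    limit = _modal_profile(x, y) if converged else None
    return Trajectory(np.asarray(times), states, converged, limit)


def run_replicator(config: GameConfig,
                   init: tuple[np.ndarray, np.ndarray],
                   params: DynamicsParams | None = None) -> Trajectory:
    """Integrate the two-population replicator dynamic from ``init``."""
    params = params or DynamicsParams()
    A, B = payoff_matrices(config)
    x = _check_simplex(init[0], "role-1 state")
    y = _check_simplex(init[1], "role-2 state")
    return _run_replicator(A, B, x, y, params)


# -- best response -------------------------------------------------------------


def _best_response_mixture(payoffs: np.ndarray) -> np.ndarray:
    best = payoffs.max()
    mask = payoffs >= best - 1e-12
    return mask / mask.sum()


def _run_best_response(A: np.ndarray, B: np.ndarray,
                       x: np.ndarray, y: np.ndarray,
                       params: DynamicsParams) -> Trajectory:
    h = params.step_size
    n_steps = int(round(params.time_horizon / h))
    record_every = max(1, n_steps // 2000)
    times, states = [0.0], [(x.copy(), y.copy())]
    converged = False
    for step in range(1, n_steps + 1):
        bx = _best_response_mixture(A @ y)
        by = _best_response_mixture(B.T @ x)
        nx = (1.0 - h) * x + h * bx
        ny = (1.0 - h) * y + h * by
        delta = max(np.abs(nx - x).max(), np.abs(ny - y).max())
        x, y = nx, ny
        if step % record_every == 0:
            times.append(float(step))
            states.append((x.copy(), y.copy()))
        if delta < params.convergence_tol:
            converged = True
            break
    if times[-1] != float(step):
        times.append(float(step))
        states.append((x.copy(), y.copy()))
    limit = _modal_profile(x, y) if converged else None
    return Trajectory(np.asarray(times), states, converged, limit)


def run_best_response(config: GameConfig,
                      init: tuple[np.ndarray, np.ndarray],
                      params: DynamicsParams | None = None) -> Trajectory:
    """Smoothed best-response dynamic (step-size fraction toward best replies)."""
    params = params or DynamicsParams()
    A, B = payoff_matrices(config)
    x = _check_simplex(init[0], "role-1 state")
    y = _check_simplex(init[1], "role-2 state")
    return _run_best_response(A, B, x, y, params)


# -- birth-death ---------------------------------------------------------------


def _sample_population(weights: np.ndarray, size: int,
                       rng: np.random.Generator) -> np.ndarray:
    return rng.choice(weights.size, size=size, p=weights)


def _run_birth_death(A: np.ndarray, B: np.ndarray,
                     x: np.ndarray, y: np.ndarray,
                     params: DynamicsParams) -> Trajectory:
    if params.seed is None:
        raise ValueError("birth-death dynamics requires a seed")
    rng = np.random.default_rng(params.seed)
    N = params.population_size
    beta, mu = params.selection_strength, params.mutation_rate
    m, n = A.shape
    pop1 = _sample_population(x, N, rng)
    pop2 = _sample_population(y, N, rng)
    n_steps = int(params.time_horizon)
    record_every = max(1, n_steps // 2000)

    def freqs():
        f1 = np.bincount(pop1, minlength=m) / N
        f2 = np.bincount(pop2, minlength=n) / N
        return f1, f2

    times, states = [0.0], [freqs()]
    for step in range(1, n_steps + 1):
        role = rng.integers(2)
        if role == 0:
            f2 = np.bincount(pop2, minlength=n) / N
            fitness = A @ f2
            pop = pop1
            n_strats = m
        else:
            f1 = np.bincount(pop1, minlength=m) / N
            fitness = B.T @ f1
            pop = pop2
            n_strats = n
        focal, model = rng.integers(N), rng.integers(N)
        if rng.random() < mu:
            pop[focal] = rng.integers(n_strats)
        else:
            gain = fitness[pop[model]] - fitness[pop[focal]]
            if rng.random() < expit(beta * gain):
                pop[focal] = pop[model]
        if step % record_every == 0:
            times.append(float(step))
            states.append(freqs())
    return Trajectory(np.asarray(times), states, converged=False)


def run_birth_death(config: GameConfig,
                    init: tuple[np.ndarray, np.ndarray],
                    params: DynamicsParams | None = None) -> Trajectory:
    """Pairwise-comparison birth-death process in two role sub-populations.

    The initial sub-populations are sampled from ``init`` under the seed, so
    identical seeds give bit-identical runs.
    """
    params = params or DynamicsParams(seed=0)
    A, B = payoff_matrices(config)
    x = _check_simplex(init[0], "role-1 state")
    y = _check_simplex(init[1], "role-2 state")
    return _run_birth_death(A, B, x, y, params)


# -- introspection -------------------------------------------------------------


def introspection_transition_matrix(A: np.ndarray, B: np.ndarray,
                                    beta: float) -> np.ndarray:
    """Markov transition matrix of single-pair introspection dynamics.

    States are joint pure profiles (i, j), flattened row-major.  Each step
    one player is picked with probability 1/2, an alternative strategy is
    drawn uniformly from that player's other strategies, and the switch is
    accepted with the Fermi probability.
    """
    m, n = A.shape
    S = m * n
    T = np.zeros((S, S))
    idx = lambda i, j: i * n + j
    for i in range(m):
        for j in range(n):
            s = idx(i, j)
            if m > 1:
                for i2 in range(m):
                    if i2 == i:
                        continue
                    p = 0.5 / (m - 1) * expit(beta * (A[i2, j] - A[i, j]))
                    T[s, idx(i2, j)] += p
            else:
                T[s, s] += 0.5
            if n > 1:
                for j2 in range(n):
                    if j2 == j:
                        continue
                    p = 0.5 / (n - 1) * expit(beta * (B[i, j2] - B[i, j]))
                    T[s, idx(i, j2)] += p
            else:
                T[s, s] += 0.5
            T[s, s] += 1.0 - T[s].sum()
    return T


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible stochastic matrix.

    Solves pi (T - I) = 0 with the normalization sum(pi) = 1 as a dense
    linear system; unique for the introspection chain at finite beta.
    """
    S = T.shape[0]
    M = (T.T - np.eye(S))
    M[-1, :] = 1.0
    b = np.zeros(S)
    b[-1] = 1.0
    pi = np.linalg.solve(M, b)
    if np.any(pi < -1e-10):
        raise RuntimeError("stationary solve produced negative probabilities")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _simulate_introspection(A: np.ndarray, B: np.ndarray, beta: float,
                            n_steps: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    m, n = A.shape
    i = int(rng.integers(m))
    j = int(rng.integers(n))
    players = rng.integers(2, size=n_steps)
    alt1 = rng.integers(max(m - 1, 1), size=n_steps)
    alt2 = rng.integers(max(n - 1, 1), size=n_steps)
    accept = rng.random(n_steps)
    counts = np.zeros((m, n))
    for t in range(n_steps):
        if players[t] == 0 and m > 1:
            i2 = alt1[t] + (alt1[t] >= i)
            if accept[t] < expit(beta * (A[i2, j] - A[i, j])):
                i = int(i2)
        elif players[t] == 1 and n > 1:
            j2 = alt2[t] + (alt2[t] >= j)
            if accept[t] < expit(beta * (B[i, j2] - B[i, j])):
                j = int(j2)
        counts[i, j] += 1
    return (counts / n_steps).ravel()


def introspection_stationary(config: GameConfig,
                             params: DynamicsParams | None = None,
                             mode: str = "exact") -> np.ndarray:
    """Long-run distribution over joint contribution profiles.

    Returns a vector of length (e1+1)*(e2+1), flattened row-major over
    (c1, c2).  ``exact`` builds the full transition matrix and solves for
    its stationary distribution; ``simulated`` estimates it from a single
    seeded run of ``time_horizon`` steps.
    """
    params = params or DynamicsParams()
    A, B = payoff_matrices(config)
    if mode == "exact":
        T = introspection_transition_matrix(A, B, params.selection_strength)
        return stationary_distribution(T)
    if mode == "simulated":
        if params.seed is None:
            raise ValueError("simulated introspection requires a seed")
        return _simulate_introspection(A, B, params.selection_strength,
                                       int(params.time_horizon), params.seed)
    raise ValueError(f"unknown mode {mode!r}; expected 'exact' or 'simulated'")


# -- export --------------------------------------------------------------------


def trajectory_to_frame(trajectory: Trajectory) -> pd.DataFrame:
    """Long-format table of a trajectory: time, role, contribution, weight."""
    rows = []
    for t, (x, y) in zip(trajectory.times, trajectory.states):
        for role, v in ((1, x), (2, y)):
            for c, w in enumerate(v):
                rows.append((t, role, c, w))
    return pd.DataFrame(rows, columns=["time", "role", "contribution", "weight"])
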