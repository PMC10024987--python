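"""Repeated play with deterministic reactive strategies.

A *reactive strategy* consists of an opening contribution for round 1 and a
response map sending the co-player's previous-round contribution to the own
contribution for the current round.  Two deterministic reactive strategies
generate an eventually periodic sequence of contribution profiles: the
joint profile of a round determines both players' next moves, so by the
pigeonhole principle a cycle is entered within (e1+1)*(e2+1) + 1 rounds.
Repeated-game payoffs are taken as per-round averages over one full cycle
(the limit-of-means criterion); finite-horizon averages over an
experiment-length run are available by passing a small ``rounds``.

Evolutionary selection over reactive strategies reuses the one-shot
machinery: a finite strategy family induces a bimatrix of cycle-average
payoffs, on which introspection or birth-death dynamics run unchanged.
Restricted to constant strategies the repeated game collapses exactly onto
the one-shot game, which serves as a built-in consistency check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .dynamics import (DynamicsParams, Trajectory, _run_birth_death,
                       introspection_transition_matrix, stationary_distribution)
from .game import GameConfig, payoff

__all__ = [
    "ReactiveStrategy",
    "RepeatedOutcome",
    "play_repeated",
    "constant_family",
    "linear_family",
    "sampled_family",
    "repeated_payoff_matrices",
    "evolve_reactive",
    "best_cycle_payoff_scan",
]


@dataclass(frozen=True)
class ReactiveStrategy:
    """Opening move plus a deterministic response to the co-player's last move.

    ``response[c]`` is the own contribution played after observing the
    co-player contribute ``c``; the tuple must cover every contribution the
    co-player can make (length ``e_other + 1``).
    """

    opening: int
    response: tuple[int, ...]

    def validate(self, config: GameConfig, role: int) -> None:
        e_self = config.endowment(role)
        e_other = config.endowment(2 if role == 1 else 1)
        if not 0 <= self.opening <= e_self:
            raise ValueError(f"opening {self.opening} outside {{0, ..., {e_self}}}")
        if len(self.response) != e_other + 1:
            raise ValueError(
                f"response map has {len(self.response)} entries, "
                f"expected {e_other + 1} (co-player contributions 0..{e_other})")
        for c, own in enumerate(self.response):
            if not 0 <= own <= e_self:
                raise ValueError(
                    f"response to co-player contribution {c} is {own}, "
                    f"outside {{0, ..., {e_self}}}")

    @classmethod
    def constant(cls, c: int, e_other: int) -> "ReactiveStrategy":
        return cls(c, (c,) * (e_other + 1))


@dataclass
class RepeatedOutcome:
    """Deterministic repeated-game trajectory and its cycle statistics."""

    per_round_profiles: list[tuple[int, int]]
    cycle_start: int                 # 0-based round index where the cycle begins
    cycle_length: int
    mean_payoffs: tuple[float, float]

    @property
    def cycle_profiles(self) -> list[tuple[int, int]]:
        return self.per_round_profiles[self.cycle_start:
                                       self.cycle_start + self.cycle_length]


def play_repeated(config: GameConfig, s1: ReactiveStrategy, s2: ReactiveStrategy,
                  rounds: int = 20) -> RepeatedOutcome:
    """Play two reactive strategies against each other for ``rounds`` rounds.

    The full deterministic trajectory is simulated until the joint profile
    recurs (guaranteed within (e1+1)*(e2+1) + 1 rounds), so the cycle is
    always detected; ``per_round_profiles`` is truncated or extended to
    exactly ``rounds`` entries.  Mean payoffs average over one full cycle,
    or over the first ``rounds`` rounds when ``rounds`` ends before the
    cycle is entered.
    """
    if rounds < 1:
        raise ValueError("rounds must be at least 1")
    s1.validate(config, role=1)
    s2.validate(config, role=2)
    horizon = (config.e1 + 1) * (config.e2 + 1) + 1
    profiles: list[tuple[int, int]] = [(s1.opening, s2.opening)]
    seen = {profiles[0]: 0}
    cycle_start = cycle_length = None
    for t in range(1, max(rounds, horizon)):
        prev1, prev2 = profiles[-1]
        nxt = (s1.response[prev2], s2.response[prev1])
        if cycle_start is None:
            if nxt in seen:
                cycle_start = seen[nxt]
                cycle_length = t - seen[nxt]
                if t >= rounds:
                    break
            else:
                seen[nxt] = t
        profiles.append(nxt)
        if cycle_start is not None and t + 1 >= rounds:
            break
    assert cycle_start is not None and cycle_length is not None

    if rounds <= cycle_start:
        window = profiles[:rounds]
    else:
        window = profiles[cycle_start:cycle_start + cycle_length]
    pays = [payoff(p, config) for p in window]
    mean = (float(np.mean([p[0] for p in pays])),
            float(np.mean([p[1] for p in pays])))
    return RepeatedOutcome(profiles[:rounds], cycle_start, cycle_length, mean)


# -- strategy families ---------------------------------------------------------


def constant_family(config: GameConfig, role: int) -> list[ReactiveStrategy]:
    """All constant strategies of one role: always contribute c."""
    e_other = config.endowment(2 if role == 1 else 1)
    return [ReactiveStrategy.constant(c, e_other)
            for c in range(config.endowment(role) + 1)]


def linear_family(config: GameConfig, role: int,
                  openings: list[int] | None = None,
                  intercepts: list[int] | None = None,
                  slopes: list[float] = (-1.0, 0.0, 0.5, 1.0),
                  ) -> list[ReactiveStrategy]:
    """Linear-response grid: response(c) = clip(a + round(b * c * e_self/e_other)).

    The co-player's contribution is rescaled to the own endowment before the
    slope applies, so slope 1 with intercept 0 is proportional matching.
    Duplicate strategies arising from clipping are removed.
    """
    e_self = config.endowment(role)
    e_other = config.endowment(2 if role == 1 else 1)
    scale = e_self / e_other
    if openings is None:
        openings = sorted({0, e_self // 2, e_self})
    if intercepts is None:
        intercepts = sorted({0, e_self // 2, e_self})
    out = {}
    for opening, a, b in itertools.product(openings, intercepts, slopes):
        resp = tuple(
            int(np.clip(a + round(b * c * scale), 0, e_self))
            for c in range(e_other + 1)
        )
        out[(opening, resp)] = ReactiveStrategy(opening, resp)
    return list(out.values())


def sampled_family(config: GameConfig, role: int, k: int,
                   seed: int) -> list[ReactiveStrategy]:
    """K uniformly random reactive strategies under a seed."""
    rng = np.random.default_rng(seed)
    e_self = config.endowment(role)
    e_other = config.endowment(2 if role == 1 else 1)
    return [
        ReactiveStrategy(
            int(rng.integers(e_self + 1)),
            tuple(int(v) for v in rng.integers(e_self + 1, size=e_other + 1)),
        )
        for _ in range(k)
    ]


def _make_family(config: GameConfig, role: int, family: str,
                 family_params: dict | None) -> list[ReactiveStrategy]:
    family_params = dict(family_params or {})
    if family == "constant":
        return constant_family(config, role)
    if family == "linear":
        return linear_family(config, role, **family_params)
    if family == "sampled":
        k = family_params.pop("k", 20)
        seed = family_params.pop("seed", None)
        if seed is None:
            raise ValueError("sampled family requires a seed")
        # decorrelate the two roles' samples
        return sampled_family(config, role, k, seed + role)
    raise ValueError(f"unknown family {family!r}")


def repeated_payoff_matrices(config: GameConfig,
                             family1: list[ReactiveStrategy],
                             family2: list[ReactiveStrategy],
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Cycle-average payoff bimatrix over two finite strategy families."""
    if not family1 or not family2:
        raise ValueError("strategy families must be non-empty")
    A = np.zeros((len(family1), len(family2)))
    B = np.zeros_like(A)
    for i, s1 in enumerate(family1):
        for j, s2 in enumerate(family2):
            out = play_repeated(config, s1, s2)
            A[i, j], B[i, j] = out.mean_payoffs
    return A, B


def evolve_reactive(config: GameConfig, family: str = "constant",
                    family_params: dict | None = None,
                    params: DynamicsParams | None = None,
                    dynamic: str = "introspection",
                    ) -> tuple[np.ndarray, list[ReactiveStrategy], list[ReactiveStrategy]]:
    """Long-run distribution of a learning dynamic over a reactive-strategy family.

    ``introspection`` returns the exact stationary distribution over joint
    strategy indices (flattened row-major, shape ``len(f1) * len(f2)``);
    ``birth_death`` returns the empirical joint frequency product of the
    final sub-population states of a seeded run.  The two families used
    (role 1, role 2) are returned alongside for index interpretation.
    """
    params = params or DynamicsParams()
    f1 = _make_family(config, 1, family, family_params)
    f2 = _make_family(config, 2, family, family_params)
    A, B = repeated_payoff_matrices(config, f1, f2)
    if dynamic == "introspection":
        if A.size > 10_000:
            raise ValueError(
                "joint strategy space too large for exact introspection; "
                "reduce the family or use the birth_death dynamic")
        T = introspection_transition_matrix(A, B, params.selection_strength)
        return stationary_distribution(T), f1, f2
    if dynamic == "birth_death":
        x = np.full(len(f1), 1.0 / len(f1))
        y = np.full(len(f2), 1.0 / len(f2))
        traj = _run_birth_death(A, B, x, y, params)
        fx, fy = traj.final_state
        return np.outer(fx, fy).ravel(), f1, f2
    raise ValueError(f"unknown dynamic {dynamic!r}")


def best_cycle_payoff_scan(config: GameConfig, family: str = "constant",
                           family_params: dict | None = None,
                           ) -> tuple[RepeatedOutcome, tuple[int, int]]:
    """Exhaustive scan for the strategy pair maximizing total cycle-average payoff.

    Returns the best outcome and the representative per-round profile it
    plays (the most frequent profile of the cycle; ties resolve
    lexicographically, and total-payoff ties resolve toward the more equal
    contribution split).
    """
    f1 = _make_family(config, 1, family, family_params)
    f2 = _make_family(config, 2, family, family_params)
    best = None
    for s1 in f1:
        for s2 in f2:
            out = play_repeated(config, s1, s2)
            total = sum(out.mean_payoffs)
            cycle = out.cycle_profiles
            rep = min(sorted(cycle), key=lambda p: (-cycle.count(p), p))
            key = (-total, abs(rep[0] - rep[1]), rep)
            if best is None or key < best[0]:
                best = (key, out, rep)
    assert best is not None
    return best[1], best[2]
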