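"""Synthetic behavioural sessions for the threshold public goods game.

Real sessions of this experiment pair participants for 20 rounds of one
treatment (game 1), then re-match every participant with a *new* partner in
the *opposite* role for another 20 rounds (game 2).  After every round both
players see each other's contributions, the collective contribution and
their payoffs.  This module generates data of exactly that shape from a
simple directional-learning agent, so downstream metrics and the
empirical-initial-condition pathway of the dynamics can be exercised
without any human-subject data.

The agent model is deliberately minimal.  Each subject opens with one of
four behaviours (contribute half the endowment, play the equal-absolute-
contributions profile, contribute nothing, or contribute uniformly at
random), drawn once per subject from a mixture.  From round 2 on the
subject repeats its previous contribution except for three adjustments:

* after a *failed* round in which the subject gave less than half its
  endowment, it raises its contribution by ``step`` with probability
  ``adjust_up_prob`` (the conditional response observed in failing
  groups);
* after a successful round that *overshot* the threshold, it lowers its
  contribution by ``step`` with probability ``adjust_down_prob``;
* in any round it instead contributes uniformly at random with
  probability ``noise_prob``.

No claim is made that this process fits human play quantitatively; it is a
stand-in that reproduces the qualitative session structure (rising success
rates, slower coordination under endowment inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibrium import select_by_heuristic
from .game import GameConfig, make_treatment, payoff

__all__ = [
    "AgentModel",
    "RECORD_COLUMNS",
    "simulate_session",
    "first_round_distribution",
    "write_records",
    "read_records",
    "validate_records",
]

OPENING_KINDS = ("erc", "eac", "zero", "random")

RECORD_COLUMNS = [
    "treatment", "game", "pair_id", "round", "role", "subject_id",
    "contribution", "collective", "success", "effective", "payoff",
]


@dataclass(frozen=True)
class AgentModel:
    """Directional-learning agent for synthetic sessions.

    ``initial_mixture`` gives the probabilities of the four opening
    behaviours in the order (half-endowment, equal-absolute profile, zero,
    uniform random).
    """

    initial_mixture: tuple[float, float, float, float] = (0.6, 0.2, 0.1, 0.1)
    adjust_up_prob: float = 0.5
    adjust_down_prob: float = 0.3
    step: int = 1
    noise_prob: float = 0.05

    def __post_init__(self) -> None:
        mix = np.asarray(self.initial_mixture, dtype=float)
        if mix.shape != (4,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("initial_mixture must be 4 non-negative weights summing to 1")
        for label, p in (("adjust_up_prob", self.adjust_up_prob),
                         ("adjust_down_prob", self.adjust_down_prob),
                         ("noise_prob", self.noise_prob)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{label} must lie in [0, 1]")
        if self.step < 1 or int(self.step) != self.step:
            raise ValueError("step must be a positive integer")


def _opening(kind: str, role: int, config: GameConfig,
             rng: np.random.Generator) -> int:
    e = config.endowment(role)
    if kind == "erc":
        return e // 2
    if kind == "eac":
        eac = select_by_heuristic(config, "EAC")
        return eac[role - 1] if eac is not None else e // 2
    if kind == "zero":
        return 0
    return int(rng.integers(e + 1))


def _random_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of range(n) with no fixed point (n >= 2)."""
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def _play_game(config: GameConfig, game: int, pairs: list[tuple[int, int]],
               opening_kind: dict[int, str], agent: AgentModel, rounds: int,
               rng: np.random.Generator, rows: list) -> None:
    for pair_id, (subj1, subj2) in enumerate(pairs):
        contribs = {
            1: _opening(opening_kind[subj1], 1, config, rng),
            2: _opening(opening_kind[subj2], 2, config, rng),
        }
        for rnd in range(1, rounds + 1):
            if rnd > 1:
                prev = dict(contribs)
                for role, subj in ((1, subj1), (2, subj2)):
                    e = config.endowment(role)
                    c = prev[role]
                    if rng.random() < agent.noise_prob:
                        c = int(rng.integers(e + 1))
                    elif not success and prev[role] < e / 2:
                        if rng.random() < agent.adjust_up_prob:
                            c = min(e, c + agent.step)
                    elif success and collective > config.theta:
                        if rng.random() < agent.adjust_down_prob:
                            c = max(0, c - agent.step)
                    contribs[role] = c
            profile = (contribs[1], contribs[2])
            collective = config.p1 * profile[0] + config.p2 * profile[1]
            success = collective >= config.theta
            effective = collective == config.theta
            pi1, pi2 = payoff(profile, config)
            for role, subj, c, pi in ((1, subj1, profile[0], pi1),
                                      (2, subj2, profile[1], pi2)):
                rows.append((config.name, game, pair_id, rnd, role, subj,
                             c, collective, int(success), int(effective), pi))


def simulate_session(config: GameConfig, n_pairs: int = 14,
                     agent: AgentModel | None = None, seed: int = 0,
                     rounds: int = 20) -> pd.DataFrame:
    """Simulate one session: game 1, partner/role re-match, game 2.

    ``2 * n_pairs`` subjects are created.  In game 1 they are paired at
    random and assigned fixed roles for ``rounds`` rounds.  In game 2 the
    roles swap (everyone who was player 1 becomes player 2 and vice versa)
    and the pairing is permuted by a random derangement so nobody meets
    their previous partner.  Identical seeds give identical records.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be at least 2 (role-swap re-matching "
                         "requires more than one pair)")
    agent = agent or AgentModel()
    rng = np.random.default_rng(seed)
    subjects = rng.permutation(2 * n_pairs)
    role1 = list(subjects[:n_pairs])     # player 1 in game 1
    role2 = list(subjects[n_pairs:])     # player 2 in game 1
    kinds = rng.choice(len(OPENING_KINDS), size=2 * n_pairs,
                       p=agent.initial_mixture)
    opening_kind = {int(s): OPENING_KINDS[k] for s, k in zip(subjects, kinds)}

    rows: list = []
    pairs_g1 = list(zip(role1, role2))
    _play_game(config, 1, pairs_g1, opening_kind, agent, rounds, rng, rows)
    # game 2: former player-2 subjects take role 1; derangement of the pair
    # indices guarantees no game-1 pair recurs
    perm = _random_derangement(n_pairs, rng)
    pairs_g2 = [(role2[i], role1[perm[i]]) for i in range(n_pairs)]
    _play_game(config, 2, pairs_g2, opening_kind, agent, rounds, rng, rows)

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return records


def first_round_distribution(records: pd.DataFrame,
                             treatment: str | None = None,
                             pool_games: bool = False,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-role normalized histograms of round-1 contributions.

    By default only game 1 is used (the uncontaminated first decision);
    ``pool_games`` also counts round 1 of game 2.  Returns weight vectors of
    length ``e_role + 1`` suitable as an empirical initial condition.
    """
    if records.empty:
        raise ValueError("empty records")
    df = records
    if treatment is not None:
        df = df[df["treatment"] == treatment]
    if df.empty:
        raise ValueError(f"no rows for treatment {treatment!r}")
    if df["treatment"].nunique() > 1:
        raise ValueError("records mix treatments; pass treatment=...")
    config = make_treatment(df["treatment"].iloc[0])
    df = df[df["round"] == 1]
    if not pool_games:
        df = df[df["game"] == 1]
    out = []
    for role in (1, 2):
        contribs = df.loc[df["role"] == role, "contribution"].to_numpy()
        if contribs.size == 0:
            raise ValueError(f"no round-1 rows for role {role}")
        counts = np.bincount(contribs, minlength=config.endowment(role) + 1)
        out.append(counts / counts.sum())
    return tuple(out)


# -- persistence ---------------------------------------------------------------


def validate_records(records: pd.DataFrame,
                     configs: dict[str, GameConfig] | None = None) -> None:
    """Check structural invariants and recompute payoffs from the game rules.

    Raises ``ValueError`` naming the first offending row group.  Unknown
    treatment labels must be supplied through ``configs``.
    """
    if records.empty:
        raise ValueError("empty records")
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    configs = configs or {}
    for treatment, df in records.groupby("treatment"):
        config = configs.get(treatment) or make_treatment(treatment)
        sizes = df.groupby(["game", "pair_id", "round"]).size()
        bad = sizes[sizes != 2]
        if not bad.empty:
            raise ValueError(
                f"treatment {treatment}: expected exactly two rows per "
                f"(game, pair, round), offending group {bad.index[0]}")
        for key, grp in df.groupby(["game", "pair_id", "round"]):
            roles = sorted(grp["role"])
            if roles != [1, 2]:
                raise ValueError(f"group {key}: roles {roles} != [1, 2]")
            grp = grp.sort_values("role")
            c1, c2 = grp["contribution"].to_numpy()
            pi1, pi2 = payoff((c1, c2), config)   # also validates ranges
            collective = config.p1 * c1 + config.p2 * c2
            row = grp.iloc[0]
            if not np.allclose(grp["collective"], collective):
                raise ValueError(f"group {key}: collective column inconsistent")
            if (bool(row["success"]) != (collective >= config.theta)
                    or bool(row["effective"]) != (collective == config.theta)):
                raise ValueError(f"group {key}: success/effective flags inconsistent")
            if not np.allclose(grp["payoff"].to_numpy(), [pi1, pi2]):
                raise ValueError(f"group {key}: payoff column inconsistent "
                                 f"with the game rules")


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write session records as CSV (lossless round trip with read_records)."""
    records.to_csv(path, index=False)


def read_records(path: str | Path,
                 configs: dict[str, GameConfig] | None = None) -> pd.DataFrame:
    """Read and validate session records from CSV."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty records file: {path}")
    records = pd.read_csv(path)
    validate_records(records, configs)
    return records
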