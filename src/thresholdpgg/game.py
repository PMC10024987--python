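"""Asymmetric two-player threshold public goods game.

Two players receive integer endowments ``e1, e2`` and simultaneously
contribute integer amounts ``c_i`` from their endowment to a common pool.
Contributions are weighted by productivity factors ``p1, p2``; the weighted
sum ``p1*c1 + p2*c2`` is the pair's *collective contribution*.  If it reaches
a threshold ``theta`` each player earns a reward ``r_i`` on top of whatever
endowment they kept; otherwise they only keep the remainder:

    pi_i = e_i - c_i + r_i   if p1*c1 + p2*c2 >= theta
    pi_i = e_i - c_i         otherwise

Five canonical treatments are provided.  One is fully symmetric; two
introduce endowment inequality (player 1 holds 2x or 3x the endowment of
player 2); two introduce productivity inequality (player 1's contributions
count 2x or 3x).  Rewards are identical across treatments and the threshold
is always the collective contribution produced when both players contribute
exactly half their endowment, so the "equal relative contributions" profile
meets the threshold exactly in every treatment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "GameConfig",
    "TREATMENTS",
    "make_treatment",
    "load_config",
    "collective_contribution",
    "payoff",
    "payoff_matrices",
    "validate_profile",
    "iter_profiles",
]


class InvalidProfileError(ValueError):
    """A contribution lies outside a player's feasible set {0, ..., e_i}."""


@dataclass(frozen=True)
class GameConfig:
    """Parameters of one treatment of the threshold public goods game.

    Parameters
    ----------
    e1, e2
        Positive integer endowments (coins).
    p1, p2
        Positive integer productivity factors multiplying each player's
        contribution in the collective contribution.
    r1, r2
        Positive rewards (coins) paid to each player when the threshold
        is reached.
    theta
        Threshold on the collective contribution.  If omitted it is derived
        from the half-endowment rule ``theta = (p1*e1 + p2*e2) / 2``.
    name
        Free-text treatment label.
    """

    e1: int
    e2: int
    p1: int = 1
    p2: int = 1
    r1: float = 10.0
    r2: float = 10.0
    theta: float | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        for label, value in (("e1", self.e1), ("e2", self.e2),
                             ("p1", self.p1), ("p2", self.p2)):
            if int(value) != value or value < 1:
                raise ValueError(f"{label} must be a positive integer, got {value!r}")
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("rewards r1, r2 must be positive")
        if self.theta is None:
            object.__setattr__(self, "theta", (self.p1 * self.e1 + self.p2 * self.e2) / 2)
        if self.theta <= 0:
            raise ValueError("threshold theta must be positive")
        if self.theta > self.p1 * self.e1 + self.p2 * self.e2:
            raise ValueError(
                "threshold unreachable: theta exceeds the collective contribution "
                "of joint full contribution"
            )

    # -- role-indexed accessors -------------------------------------------------

    def endowment(self, role: int) -> int:
        self._check_role(role)
        return self.e1 if role == 1 else self.e2

    def productivity(self, role: int) -> int:
        self._check_role(role)
        return self.p1 if role == 1 else self.p2

    def reward(self, role: int) -> float:
        self._check_role(role)
        return self.r1 if role == 1 else self.r2

    @staticmethod
    def _check_role(role: int) -> None:
        if role not in (1, 2):
            raise ValueError(f"role must be 1 or 2, got {role!r}")

    @property
    def half_profile(self) -> tuple[int, int]:
        """The equal-relative-contributions profile (e1/2, e2/2).

        For odd endowments the exact half is not an integer; the floor is
        returned and :attr:`has_integer_half` is False.
        """
        return (self.e1 // 2, self.e2 // 2)

    @property
    def has_integer_half(self) -> bool:
        return self.e1 % 2 == 0 and self.e2 % 2 == 0

    def with_overrides(self, **overrides) -> "GameConfig":
        """Return a copy with fields replaced; theta is re-derived from the
        half-endowment rule unless explicitly overridden."""
        if overrides and "theta" not in overrides:
            overrides["theta"] = None
        return replace(self, **overrides)

    def to_dict(self) -> dict:
        return {
            "treatment": self.name, "e1": self.e1, "e2": self.e2,
            "p1": self.p1, "p2": self.p2, "r1": self.r1, "r2": self.r2,
            "theta": self.theta,
        }


#: Default parameters of the five canonical treatments.  Endowment ratios are
#: 2:1 and 3:1 in the endowment-inequality treatments, productivity ratios 2:1
#: and 3:1 in the productivity-inequality treatments, rewards are constant
#: across treatments, and theta always follows the half-endowment rule
#: (hence 12, 12, 12, 12 and 16).
TREATMENTS: Mapping[str, GameConfig] = {
    "full_equality": GameConfig(12, 12, 1, 1, name="full_equality"),
    "moderate_endowment": GameConfig(16, 8, 1, 1, name="moderate_endowment"),
    "strong_endowment": GameConfig(18, 6, 1, 1, name="strong_endowment"),
    "moderate_productivity": GameConfig(8, 8, 2, 1, name="moderate_productivity"),
    "strong_productivity": GameConfig(8, 8, 3, 1, name="strong_productivity"),
}


def make_treatment(name: str, **overrides) -> GameConfig:
    """Return the default :class:`GameConfig` for a canonical treatment.

    ``overrides`` replace individual fields; unless ``theta`` itself is
    overridden it is re-derived from the half-endowment rule so that the
    equal-relative-contributions profile still meets the threshold exactly.
    """
    try:
        base = TREATMENTS[name]
    except KeyError:
        raise ValueError(
            f"unknown treatment {name!r}; expected one of {sorted(TREATMENTS)}"
        ) from None
    return base.with_overrides(**overrides) if overrides else base


def load_config(path: str | Path) -> GameConfig:
    """Read a game configuration from a YAML or JSON file.

    Recognized keys: ``treatment`` (canonical name used as a base, optional),
    ``e1 e2 p1 p2 r1 r2 theta`` (all optional when a treatment is given;
    ``theta`` is derived from the half-endowment rule when absent).
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    treatment = data.pop("treatment", None)
    fields = {k: v for k, v in data.items()
              if k in ("e1", "e2", "p1", "p2", "r1", "r2", "theta")}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if treatment is not None:
        return make_treatment(treatment, **fields)
    if "e1" not in fields or "e2" not in fields:
        raise ValueError("config without a treatment must give e1 and e2")
    return GameConfig(name=str(path.stem), **fields)


# -- payoffs -------------------------------------------------------------------


def validate_profile(profile: tuple[int, int], config: GameConfig) -> tuple[int, int]:
    """Check a contribution profile against the players' endowments."""
    c1, c2 = profile
    for role, (c, e) in enumerate([(c1, config.e1), (c2, config.e2)], start=1):
        if int(c) != c or not 0 <= c <= e:
            raise InvalidProfileError(
                f"player {role}: contribution {c!r} outside {{0, ..., {e}}}"
            )
    return int(c1), int(c2)


def collective_contribution(profile: tuple[int, int], config: GameConfig) -> float:
    """Productivity-weighted sum of contributions, p1*c1 + p2*c2."""
    c1, c2 = validate_profile(profile, config)
    return config.p1 * c1 + config.p2 * c2


def payoff(profile: tuple[int, int], config: GameConfig) -> tuple[float, float]:
    """Payoff pair (pi1, pi2) for a pure contribution profile.

    The threshold comparison is non-strict: reaching theta exactly earns
    the reward.
    """
    c1, c2 = validate_profile(profile, config)
    met = config.p1 * c1 + config.p2 * c2 >= config.theta
    pi1 = config.e1 - c1 + (config.r1 if met else 0.0)
    pi2 = config.e2 - c2 + (config.r2 if met else 0.0)
    return pi1, pi2


def iter_profiles(config: GameConfig) -> Iterator[tuple[int, int]]:
    """Iterate over all (e1+1)*(e2+1) pure contribution profiles."""
    for c1 in range(config.e1 + 1):
        for c2 in range(config.e2 + 1):
            yield (c1, c2)


def payoff_matrices(config: GameConfig) -> tuple[np.ndarray, np.ndarray]:
    """Dense bimatrix representation of the game.

    Returns ``(A, B)`` of shape ``(e1+1, e2+1)`` where ``A[c1, c2]`` is
    player 1's payoff and ``B[c1, c2]`` player 2's.
    """
    c1 = np.arange(config.e1 + 1)[:, None]
    c2 = np.arange(config.e2 + 1)[None, :]
    met = config.p1 * c1 + config.p2 * c2 >= config.theta
    A = config.e1 - c1 + np.where(met, config.r1, 0.0)
    B = config.e2 - c2 + np.where(met, config.r2, 0.0)
    return A.astype(float), B.astype(float)
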