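"""Pure Nash equilibria of the one-shot game and equilibrium-selection heuristics.

The one-shot threshold public goods game generically has two kinds of pure
equilibria: a *defective* equilibrium (0, 0) in which nobody contributes
(present only when no single player can profitably reach the threshold
alone), and a set of *cooperative* equilibria in which the collective
contribution meets the threshold and neither player can gain by cutting
back.  With equal productivities every cooperative equilibrium hits the
threshold exactly; with unequal productivities small integer overshoots can
occur when the less productive player already contributes nothing.

Because cooperative equilibria are plentiful, players face a coordination
problem on top of the social dilemma.  Five selection heuristics are
implemented, each picking a focal profile out of the cooperative set:

* ``EAC`` — equal absolute contributions, c1 == c2;
* ``ERC`` — equal relative contributions, c1/e1 == c2/e2 (the half-endowment
  profile under the canonical threshold rule);
* ``ECC`` — equal effective (collective) contributions, p1*c1 == p2*c2;
* ``EP``  — equal payoffs pi1 == pi2, falling back to the cooperative
  equilibrium minimizing |pi1 - pi2| when no exact solution exists;
* ``MCP`` — maximal collective payoff pi1 + pi2, ties broken toward the
  more equal split (smaller |c1 - c2|).

The Nash convention is the standard weak one: a profile is an equilibrium
when no unilateral deviation *strictly* improves the deviator's payoff.
Strictness is reported separately (``strict`` when every deviation strictly
hurts, ``weak`` when some deviation ties).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .game import GameConfig, iter_profiles, payoff, validate_profile

__all__ = [
    "Equilibrium",
    "EquilibriumSet",
    "HEURISTICS",
    "best_responses",
    "is_nash",
    "enumerate_pure_nash",
    "select_by_heuristic",
    "heuristic_table",
]

HEURISTICS = ("EAC", "ERC", "ECC", "EP", "MCP")


@dataclass(frozen=True)
class Equilibrium:
    profile: tuple[int, int]
    kind: str          # "cooperative" | "defective"
    strictness: str    # "strict" | "weak"
    payoffs: tuple[float, float]


@dataclass
class EquilibriumSet:
    """Classified pure Nash equilibria of one game configuration."""

    config: GameConfig
    equilibria: list[Equilibrium] = field(default_factory=list)

    @property
    def cooperative(self) -> list[Equilibrium]:
        return [eq for eq in self.equilibria if eq.kind == "cooperative"]

    @property
    def defective(self) -> list[Equilibrium]:
        return [eq for eq in self.equilibria if eq.kind == "defective"]

    @property
    def profiles(self) -> set[tuple[int, int]]:
        return {eq.profile for eq in self.equilibria}

    def __len__(self) -> int:
        return len(self.equilibria)

    def __contains__(self, profile: tuple[int, int]) -> bool:
        return tuple(profile) in self.profiles

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "equilibria": [
                {
                    "c1": eq.profile[0], "c2": eq.profile[1],
                    "class": eq.kind, "strictness": eq.strictness,
                    "pi1": eq.payoffs[0], "pi2": eq.payoffs[1],
                }
                for eq in self.equilibria
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def best_responses(config: GameConfig, role: int, opponent_contribution: int) -> set[int]:
    """All own contributions maximizing own payoff against a fixed opponent move.

    Evaluated by exhaustive enumeration over the player's feasible set.
    """
    GameConfig._check_role(role)
    other = 2 if role == 1 else 1
    if not 0 <= opponent_contribution <= config.endowment(other):
        raise ValueError(
            f"opponent contribution {opponent_contribution} outside "
            f"{{0, ..., {config.endowment(other)}}}"
        )
    payoffs = {}
    for c in range(config.endowment(role) + 1):
        profile = (c, opponent_contribution) if role == 1 else (opponent_contribution, c)
        payoffs[c] = payoff(profile, config)[role - 1]
    best = max(payoffs.values())
    return {c for c, v in payoffs.items() if v == best}


def is_nash(config: GameConfig, profile: tuple[int, int]) -> tuple[bool, str]:
    """Best-response check of one profile by exhaustive deviation enumeration.

    Returns ``(is_equilibrium, strictness)`` with strictness in
    ``{"strict", "weak", "none"}``.
    """
    c1, c2 = validate_profile(profile, config)
    strict = True
    for role, own, opp in ((1, c1, c2), (2, c2, c1)):
        base = payoff((own, opp) if role == 1 else (opp, own), config)[role - 1]
        for dev in range(config.endowment(role) + 1):
            if dev == own:
                continue
            alt = payoff((dev, opp) if role == 1 else (opp, dev), config)[role - 1]
            if alt > base:
                return False, "none"
            if alt == base:
                strict = False
    return True, ("strict" if strict else "weak")


def enumerate_pure_nash(config: GameConfig) -> EquilibriumSet:
    """Exhaustive scan of all (e1+1)*(e2+1) profiles for pure Nash equilibria.

    Equilibria are classified ``cooperative`` when the collective
    contribution meets the threshold, else ``defective``.  A below-threshold
    equilibrium is necessarily (0, 0): any positive contribution that fails
    the threshold is strictly wasteful and would be withdrawn.
    """
    result = EquilibriumSet(config)
    for profile in iter_profiles(config):
        ok, strictness = is_nash(config, profile)
        if not ok:
            continue
        met = (config.p1 * profile[0] + config.p2 * profile[1]) >= config.theta
        result.equilibria.append(
            Equilibrium(profile, "cooperative" if met else "defective",
                        strictness, payoff(profile, config))
        )
    return result


def _cooperative_profiles(config: GameConfig,
                          equilibria: EquilibriumSet | None) -> list[tuple[int, int]]:
    eqs = equilibria if equilibria is not None else enumerate_pure_nash(config)
    return [eq.profile for eq in eqs.cooperative]


def select_by_heuristic(config: GameConfig, heuristic: str, *,
                        nearest: bool = False,
                        equilibria: EquilibriumSet | None = None,
                        ) -> tuple[int, int] | None:
    """Apply one selection heuristic to the cooperative equilibrium set.

    Parameters
    ----------
    heuristic
        One of ``EAC``, ``ERC``, ``ECC``, ``EP``, ``MCP`` (see module
        docstring).
    nearest
        For the exact-condition heuristics (EAC, ERC, ECC): when the exact
        integer condition has no solution inside the cooperative set, return
        the cooperative equilibrium minimizing the condition's residual
        instead of ``None``.
    equilibria
        Pre-computed equilibrium set to avoid re-enumeration.

    Returns ``None`` when the cooperative set is empty, or when an
    exact-condition heuristic has no solution and ``nearest`` is off.
    """
    if heuristic not in HEURISTICS:
        raise ValueError(f"unknown heuristic {heuristic!r}; expected one of {HEURISTICS}")
    coop = _cooperative_profiles(config, equilibria)
    if not coop:
        return None

    if heuristic in ("EAC", "ERC", "ECC"):
        residual = {
            "EAC": lambda c: abs(c[0] - c[1]),
            "ERC": lambda c: abs(c[0] / config.e1 - c[1] / config.e2),
            "ECC": lambda c: abs(config.p1 * c[0] - config.p2 * c[1]),
        }[heuristic]
        exact = [c for c in coop if residual(c) == 0]
        if exact:
            return min(exact)   # lexicographic, relevant only for degenerate configs
        if nearest:
            return min(coop, key=lambda c: (residual(c), c))
        return None

    if heuristic == "EP":
        def gap(c):
            pi1, pi2 = payoff(c, config)
            return abs(pi1 - pi2)
        # exact equal-payoff solution when one exists, else minimal payoff gap
        return min(coop, key=lambda c: (gap(c), c))

    # MCP: maximal collective payoff, ties toward the more equal split
    def mcp_key(c):
        pi1, pi2 = payoff(c, config)
        return (-(pi1 + pi2), abs(c[0] - c[1]), c)
    return min(coop, key=mcp_key)


def heuristic_table(config: GameConfig, *, nearest: bool = False) -> dict:
    """Profiles selected by every heuristic, as a JSON-ready mapping."""
    eqs = enumerate_pure_nash(config)
    table = {}
    for h in HEURISTICS:
        sel = select_by_heuristic(config, h, nearest=nearest, equilibria=eqs)
        if sel is None:
            table[h] = None
        else:
            pi1, pi2 = payoff(sel, config)
            table[h] = {"c1": sel[0], "c2": sel[1], "pi1": pi1, "pi2": pi2}
    return table
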