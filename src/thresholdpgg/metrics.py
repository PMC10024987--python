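"""Descriptive outcome measures for threshold public goods sessions.

A *group* is one pair within one game (the same two subjects re-matched in
game 2 count as new groups).  A round is *successful* when the pair's
collective contribution meets or exceeds the threshold and *effective* when
it matches the threshold exactly, so effective rounds are a subset of
successful ones.

Aggregation is group-first: per-group means over that group's rounds are
computed first and then averaged across groups, so groups with unequal
round counts carry equal weight.  Failing rounds are classified against the
half-endowment (equal-relative-contributions) baseline: which of the two
players, if any, contributed less than half their endowment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .game import GameConfig, make_treatment

__all__ = [
    "MetricsSummary",
    "success_metrics",
    "round_curves",
    "contribution_summary",
    "failure_categories",
    "conditional_response",
    "summarize",
]

FAILURE_CATEGORIES = ("only_p1_low", "only_p2_low", "both_low", "other")

GROUP_KEYS = ["treatment", "game", "pair_id"]


def _config_for(treatment: str,
                configs: dict[str, GameConfig] | None) -> GameConfig:
    if configs and treatment in configs:
        return configs[treatment]
    return make_treatment(treatment)


def _pair_rounds(records: pd.DataFrame) -> pd.DataFrame:
    """One row per (group, round) with both contributions side by side."""
    if records.empty:
        raise ValueError("empty records")
    wide = records.pivot_table(
        index=GROUP_KEYS + ["round", "collective", "success", "effective"],
        columns="role", values="contribution", aggfunc="first",
    ).reset_index()
    return wide.rename(columns={1: "c1", 2: "c2"})


def success_metrics(records: pd.DataFrame, *, bootstrap: int = 0,
                    seed: int | None = None) -> pd.DataFrame:
    """Per-treatment success and effective rates (group-first averaging).

    With ``bootstrap > 0``, percentile confidence intervals over groups are
    attached (columns ``success_lo/hi``, ``effective_lo/hi``), resampling
    groups with replacement under ``seed``.
    """
    rounds = _pair_rounds(records)
    per_group = rounds.groupby(GROUP_KEYS)[["success", "effective"]].mean()
    out = []
    rng = np.random.default_rng(seed)
    for treatment, grp in per_group.groupby(level="treatment"):
        row = {"treatment": treatment,
               "n_groups": len(grp),
               "success_rate": grp["success"].mean(),
               "effective_rate": grp["effective"].mean()}
        if bootstrap > 0:
            vals = grp.to_numpy()
            idx = rng.integers(len(vals), size=(bootstrap, len(vals)))
            means = vals[idx].mean(axis=1)
            for k, col in enumerate(["success", "effective"]):
                lo, hi = np.percentile(means[:, k], [2.5, 97.5])
                row[f"{col}_lo"], row[f"{col}_hi"] = lo, hi
        out.append(row)
    return pd.DataFrame(out)


def round_curves(records: pd.DataFrame) -> pd.DataFrame:
    """Success/effective rate per round index, averaged across groups."""
    rounds = _pair_rounds(records)
    curves = (rounds.groupby(["treatment", "round"])[["success", "effective"]]
              .mean().reset_index())
    return curves.rename(columns={"success": "success_rate",
                                  "effective": "effective_rate"})


def contribution_summary(records: pd.DataFrame,
                         configs: dict[str, GameConfig] | None = None,
                         ) -> pd.DataFrame:
    """Mean absolute and relative (c / e_role) contribution per treatment and role."""
    if records.empty:
        raise ValueError("empty records")
    out = []
    for (treatment, role), grp in records.groupby(["treatment", "role"]):
        config = _config_for(treatment, configs)
        mean_abs = grp["contribution"].mean()
        out.append({"treatment": treatment, "role": role,
                    "mean_absolute": mean_abs,
                    "mean_relative": mean_abs / config.endowment(role)})
    return pd.DataFrame(out)


def failure_categories(records: pd.DataFrame,
                       configs: dict[str, GameConfig] | None = None,
                       ) -> pd.DataFrame:
    """Classify failing rounds against the half-endowment baseline.

    Categories: only player 1 below half endowment, only player 2 below,
    both below, or neither (``other`` — an anomaly with equal
    productivities, where missing the threshold forces someone below half).
    Counts partition the failing rounds of each treatment.
    """
    rounds = _pair_rounds(records)
    failing = rounds[rounds["success"] == 0]
    out = []
    for treatment in rounds["treatment"].unique():
        config = _config_for(treatment, configs)
        sub = failing[failing["treatment"] == treatment]
        low1 = sub["c1"] < config.e1 / 2
        low2 = sub["c2"] < config.e2 / 2
        counts = {
            "only_p1_low": int((low1 & ~low2).sum()),
            "only_p2_low": int((~low1 & low2).sum()),
            "both_low": int((low1 & low2).sum()),
            "other": int((~low1 & ~low2).sum()),
        }
        out.append({"treatment": treatment, "n_failing": len(sub), **counts})
    return pd.DataFrame(out)


def conditional_response(records: pd.DataFrame,
                         configs: dict[str, GameConfig] | None = None,
                         ) -> pd.DataFrame:
    """P(raise contribution next round | this round failed and own c < e/2).

    Transitions are within-game, within-pair only; the last round of each
    game has no successor and is excluded.  When no transition qualifies
    the probability is NaN (undefined), never 0.
    """
    if records.empty:
        raise ValueError("empty records")
    df = records.sort_values(GROUP_KEYS + ["role", "round"])
    out = []
    for treatment, sub in df.groupby("treatment"):
        config = _config_for(treatment, configs)
        num = den = 0
        for (_, _, _, role), traj in sub.groupby(GROUP_KEYS + ["role"]):
            c = traj["contribution"].to_numpy()
            success = traj["success"].to_numpy().astype(bool)
            half = config.endowment(int(role)) / 2
            qualifies = (~success[:-1]) & (c[:-1] < half)
            den += int(qualifies.sum())
            num += int((qualifies & (c[1:] > c[:-1])).sum())
        out.append({"treatment": treatment,
                    "probability": num / den if den else np.nan,
                    "numerator": num, "denominator": den})
    return pd.DataFrame(out)


@dataclass
class MetricsSummary:
    """Bundle of all descriptive measures for one record set."""

    rates: pd.DataFrame
    curves: pd.DataFrame
    contributions: pd.DataFrame
    failures: pd.DataFrame
    conditional: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "rates": self.rates.to_dict(orient="records"),
            "curves": self.curves.to_dict(orient="records"),
            "contributions": self.contributions.to_dict(orient="records"),
            "failures": self.failures.to_dict(orient="records"),
            "conditional": self.conditional.replace({np.nan: None})
                               .to_dict(orient="records"),
        }


def summarize(records: pd.DataFrame,
              configs: dict[str, GameConfig] | None = None,
              ) -> MetricsSummary:
    """Compute every measure in one pass."""
    return MetricsSummary(
        rates=success_metrics(records),
        curves=round_curves(records),
        contributions=contribution_summary(records, configs),
        failures=failure_categories(records, configs),
        conditional=conditional_response(records, configs),
    )
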