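# Methods

## The game

Two players `i = 1, 2` hold integer endowments `e_i ≥ 1`, contribute
`c_i ∈ {0, …, e_i}` simultaneously, and earn

```
π_i = e_i − c_i + r_i · 1[p1·c1 + p2·c2 ≥ θ]
```

with integer productivities `p_i ≥ 1`, rewards `r_i > 0` and threshold
`θ > 0`. The threshold comparison is non-strict: meeting `θ` exactly earns
the reward. Contributions are integers only; configurations with odd
endowments are accepted, but then no integer profile realises exact
half-endowment play (`GameConfig.has_integer_half` flags this).

### Canonical treatments

| treatment             | e        | p      | r  | θ  |
|-----------------------|----------|--------|----|----|
| full_equality         | (12, 12) | (1, 1) | 10 | 12 |
| moderate_endowment    | (16, 8)  | (1, 1) | 10 | 12 |
| strong_endowment      | (18, 6)  | (1, 1) | 10 | 12 |
| moderate_productivity | (8, 8)   | (2, 1) | 10 | 12 |
| strong_productivity   | (8, 8)   | (3, 1) | 10 | 16 |

The defining constraints are the 2:1 / 3:1 endowment ratios, the 2:1 / 3:1
productivity ratios, a reward held constant across treatments, and the
half-endowment threshold rule `θ = (p1·e1 + p2·e2) / 2`, which makes the
equal-relative-contributions profile `(e1/2, e2/2)` meet the threshold
exactly in every treatment. The magnitudes themselves are this package's
defaults, chosen so that endowments are even (half-endowment profiles are
integral), every selection-heuristic profile of interest is an integer
equilibrium, and the qualitative equilibrium structure discussed below
holds. All values can be overridden via `make_treatment(name, ...)` or a
YAML/JSON config file.

## Equilibrium analysis

`enumerate_pure_nash` scans all `(e1+1)(e2+1)` profiles and applies an
exhaustive unilateral-deviation check. The Nash convention is weak: a
profile is an equilibrium when no deviation *strictly* improves the
deviator; strictness (`strict` / `weak`) is reported separately. Any
below-threshold equilibrium is necessarily `(0, 0)` (a positive failing
contribution is strictly wasteful), so equilibria are classified
`defective` = (0,0) below threshold, `cooperative` = threshold met.

At the defaults, `(0, 0)` is a strict equilibrium in the three
equal-productivity treatments and not an equilibrium under productivity
inequality, where the productive player covers the threshold alone at a
profit (e.g. `c1 = 6`, cost 6 < r = 10). Cooperative equilibria with
`p = (1, 1)` all satisfy `c1 + c2 = θ`; with unequal productivities small
overshoots occur only when the weak player already contributes 0.

### Selection heuristics

All heuristics search the cooperative equilibrium set only:

* **EAC** `c1 = c2`; **ERC** `c1/e1 = c2/e2`; **ECC** `p1·c1 = p2·c2`.
  These are exact integer conditions; when no cooperative equilibrium
  satisfies them the selector returns `None` rather than rounding
  (e.g. ECC under strong_productivity would need `c1 = 8/3`). An optional
  `nearest` mode returns the equilibrium minimizing the condition's
  residual instead.
* **EP** `π1 = π2`, falling back to the minimal payoff gap `|π1 − π2|`
  when no exact solution exists (under strong_endowment the closest
  cooperative equilibrium is `(10, 2)` with gap 4).
* **MCP** maximal `π1 + π2`; ties break toward the smaller `|c1 − c2|`,
  then lexicographically. Total payoff depends on profiles only through
  `−(c1 + c2)`, so MCP favours the cheapest way to reach the threshold —
  under productivity inequality, loading contributions onto the productive
  player (`(6, 0)` with total 30 under moderate_productivity, versus 28 at
  the equal split).

ERC always selects the half-endowment profile (a direct consequence of the
threshold rule), and EAC agrees with ERC exactly when endowments are equal
— the formal core of why coordination is harder under endowment
inequality: the two natural focal rules point at different equilibria.

## One-shot dynamics

The strategy space per role is the full set of contribution levels; the
state is a pair of mixed strategies `(x, y)`. The exact update rules are
the standard formulations from the evolutionary-dynamics literature:

* **Replicator** (two-population): `ẋ_a = x_a[(A y)_a − xᵀA y]` and
  symmetrically for `y` with `Bᵀx`. Integrated with fixed-step RK4,
  `dt = 0.01`, horizon 2000 time units, convergence when the per-step
  state change (max-norm) falls below `1e−8`. RK4 drift off the simplex is
  renormalized each step; drift beyond `1e−6` aborts with a diagnostic (it
  never occurs at these step sizes).
* **Best response** (smoothed, discrete time): each step the state moves a
  fraction `step_size` toward the uniform mixture over current pure best
  responses (payoff ties within `1e−12` split equally).
* **Birth–death** (pairwise comparison): two sub-populations of
  `N = 100` individuals per role. Each step one role is picked at random,
  then a focal and a model individual; the focal copies the model with the
  Fermi probability `1/(1 + exp(−β(π_model − π_focal)))`, payoffs being
  expectations against the co-role's current frequency vector; with
  probability `μ` the focal instead mutates to a uniform random strategy.
  Seeded and bit-reproducible.
* **Introspection**: a single pair; each step one player (probability 1/2)
  draws one of their other contributions uniformly at random and switches
  with the Fermi probability. This yields an irreducible aperiodic Markov
  chain over joint profiles for finite β; the exact stationary
  distribution solves `π(T − I) = 0` as a dense linear system. At `β = 0`
  the chain is a symmetric random walk and the stationary distribution is
  exactly uniform. A simulated mode estimates occupancy from a seeded run
  (total variation ≈ 0.02 against the exact solution at 10⁶ steps).

Defaults: `β = 1`, `μ = 0.01`, `N = 100`, `step_size = 0.01`,
`time_horizon = 2000` (continuous time for the replicator, update count
for the discrete dynamics), convergence tolerance `1e−8` — smooth,
desk-scale convergence for all five treatments.

Initial conditions: `uniform` (equal weight on every level), `random`
(flat Dirichlet per role, seeded), `empirical` (a normalized per-role
weight vector, typically the first-round histogram of session records).

Computed behaviour at the defaults (asserted by the test suite): from
uniform initial conditions the replicator converges to mutual defection in
the three equal-productivity treatments, and under productivity inequality
to a cooperative equilibrium carried almost entirely by the productive
player — `(6, 0)` under moderate and `(5, 1)` under strong productivity
inequality (in the latter the weak player retains a single token coin;
`(5, 1)` is strictly stable and its basin contains the uniform point).
From initial conditions at or tightly concentrated on the half-endowment
profile, all four dynamics keep that outcome (exactly for the
deterministic ones, with probability 1 at `μ = 0` for the stochastic
ones) — the mechanism by which empirical first-round behaviour repairs the
prediction of naive uniform/random initializations.

## Repeated game

A reactive strategy is an opening contribution plus a deterministic
response map over the co-player's previous contribution. Stochastic
responses are excluded deliberately: determinism makes every pairing's
play eventually periodic (the joint profile determines the next profile,
so a cycle is entered within `(e1+1)(e2+1) + 1` rounds) and payoff
evaluation exact. Repeated payoffs are cycle averages (limit of means; no
discounting); finite-horizon averages over an experiment-length run are
available by passing a small `rounds`.

Three tractable strategy families are exposed: **constant** (one strategy
per contribution level; restricting the repeated game to this family
reproduces the one-shot bimatrix entry-for-entry, which the tests assert
exactly), **linear** (a small grid of opening/intercept/slope responses on
the endowment-rescaled co-contribution), and **sampled** (K random
response maps under a seed). Evolution over a family reuses the one-shot
machinery on the cycle-average bimatrix — exact introspection when the
joint space is ≤ 10⁴ states, the birth–death process otherwise.
`best_cycle_payoff_scan` searches a family exhaustively for the pair
maximizing total cycle-average payoff; for the constant family this lands
on a maximal-total-payoff cooperative one-shot equilibrium.

## Synthetic sessions

`simulate_session` emulates the session structure of behavioural
experiments on this game: `2·n_pairs` subjects, random pairing and role
assignment, 20 rounds with fixed partner and role (game 1), then a
re-match in which every subject takes the opposite role and a random
*derangement* of the pair indices guarantees nobody meets their game-1
partner again (game 2). The real matching protocols of laboratory studies
are more constrained; the derangement scheme is this package's stand-in.

The agent is a deliberately simple directional learner. Openings are drawn
once per subject from a mixture over four behaviours — half-endowment
(ERC), the EAC equilibrium profile, zero, uniform random — with default
weights (0.6, 0.2, 0.1, 0.1). From round 2 each subject repeats its last
contribution except: with probability `noise_prob = 0.05` it plays
uniformly at random; otherwise, after a failed round in which it gave less
than half its endowment it raises its contribution by `step = 1` with
probability `adjust_up_prob = 0.5`, and after an overshooting success it
lowers it by `step` with probability `adjust_down_prob = 0.3`. These
defaults produce cohorts whose success rates rise over rounds.

What the generator does *not* emulate: human heterogeneity beyond the
four opening types, any strategic response to the co-player's identity or
history (beyond the last round's group outcome), wealth effects, framing,
or fairness reasoning. Tests passing on this data show that the metrics
and the empirical-initial-condition pathway are computed correctly, not
that the agent model describes human play.

## Metrics conventions

* A **group** is one pair within one game; game-2 re-matches count as new
  groups. Rates average group means first, then across groups, so groups
  with unequal round counts weigh equally.
* **Success** is collective contribution ≥ θ; **effective** is equality;
  effective ⇒ success row-wise.
* **Failure categories** compare each player's contribution with half
  their endowment (the ERC baseline): only player 1 low, only player 2
  low, both low, neither (`other`; impossible-by-arithmetic for failing
  rounds at `p = (1, 1)` canonical settings and flagged as an anomaly
  there). The categories partition failing rounds.
* **Conditional response** is the empirical probability of raising one's
  contribution in the next round given a failed round with own
  contribution below half endowment. Transitions are within-game,
  within-pair; the last round of each game is excluded as an antecedent.
  With no qualifying transition the probability is NaN (undefined), never
  0; numerator and denominator are always reported.
* Optional bootstrap confidence intervals resample groups with
  replacement (percentile method, seeded).

Record files are plain CSV; reading re-validates every invariant and
recomputes payoffs from the rules, rejecting tampered files with the
offending row group named.

## Reproducibility

Every stochastic stage takes an explicit seed; the CLI and the acceptance
script derive per-stage sub-seeds as `sha256(global_seed | stage | label)
mod 2³¹`, so one global seed fixes all outputs while keeping stages
statistically decoupled.

## Known limitations

* Only pure-strategy equilibria are enumerated; mixed equilibria and
  refinement concepts (risk dominance, trembling hand) are out of scope.
* The repeated-game analysis covers deterministic memory-one reactive
  strategies in three finite families, not the full reactive-strategy
  continuum or longer memories.
* The replicator integrator is fixed-step; for the 13–19-point simplices
  used here this is accurate and fast, but stiff payoff scales (rewards
  orders of magnitude above endowments) may need a smaller `step_size`.
* Exact introspection scales as the cube of the joint profile count; it is
  instantaneous at the defaults but not intended for endowments beyond a
  few hundred.
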