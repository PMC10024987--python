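# thresholdpgg

Analysis toolkit for **asymmetric two-player threshold public goods games**
— a minimal coordination model of how unequal partners split the cost of a
joint goal.

Two players receive integer endowments `e1`, `e2` and simultaneously
contribute amounts `c_i ∈ {0, 1, …, e_i}` to a common pool. Contributions
are weighted by productivity factors `p1`, `p2`; if the *collective
contribution* `p1·c1 + p2·c2` reaches a threshold `θ`, each player earns a
reward `r_i` on top of the endowment they kept:

```
π_i = e_i − c_i + r_i   if p1·c1 + p2·c2 ≥ θ
π_i = e_i − c_i         otherwise
```

The game typically has a *defective* equilibrium (nobody contributes) and
many *cooperative* equilibria that meet the threshold but split the cost
differently — so on top of the social dilemma the players face an
equilibrium-selection problem. The package is aimed at researchers in
behavioural game theory and the evolution of cooperation who want to
analyse this game and test evolutionary/learning models against
experiment-shaped data:

* **`game`** — payoffs and five canonical treatments (full equality,
  moderate/strong endowment inequality with 2:1 / 3:1 endowment ratios,
  moderate/strong productivity inequality with 2:1 / 3:1 productivity
  ratios; equal rewards; `θ` always set so that contributing half of each
  endowment meets it exactly).
* **`equilibrium`** — exhaustive pure-Nash enumeration and classification,
  plus five selection heuristics: equal absolute contributions (EAC), equal
  relative contributions (ERC), equal effective contributions (ECC), equal
  payoffs (EP), maximal collective payoff (MCP).
* **`dynamics`** — two-population replicator, smoothed best response, a
  Fermi-rule birth–death process and single-pair introspection dynamics,
  with uniform, random or empirical initial conditions.
* **`repeated`** — deterministic reactive strategies (opening move plus a
  response to the co-player's last contribution), cycle detection,
  limit-of-means payoffs, and evolutionary selection over strategy
  families.
* **`experiment` / `metrics`** — a synthetic session generator emulating
  the paired 20-round / role-swap / partner-change design of behavioural
  studies of this game, and the standard outcome measures (success and
  effective rates, absolute/relative contributions, failure taxonomy,
  conditional adjustment after failure).

## Worked example

```python
from thresholdpgg import make_treatment, enumerate_pure_nash, heuristic_table

cfg = make_treatment("moderate_endowment")   # e=(16,8), p=(1,1), r=10, θ=12
eqs = enumerate_pure_nash(cfg)
print(sorted(e.profile for e in eqs.equilibria))
print(heuristic_table(cfg)["ERC"], heuristic_table(cfg)["EAC"])
```

prints

```
[(0, 0), (4, 8), (5, 7), (6, 6), (7, 5), (8, 4), (9, 3), (10, 2)]
{'c1': 8, 'c2': 4, 'pi1': 18.0, 'pi2': 14.0} {'c1': 6, 'c2': 6, 'pi1': 20.0, 'pi2': 12.0}
```

Reading: besides full defection `(0, 0)` the treatment has seven
cooperative equilibria on the line `c1 + c2 = 12`. The rich player's
half-endowment is 8 and the poor player's is 4, so the ERC heuristic picks
`(8, 4)` (payoffs 18 and 14) while EAC picks `(6, 6)` — the two focal
rules disagree exactly when endowments are unequal, which is the
coordination problem this game isolates. Under full equality or
productivity inequality both rules select the same profile.

The same analysis is available from the shell:

```sh
thresholdpgg equilibria --treatment moderate_endowment
thresholdpgg dynamics --treatment full_equality --dynamic replicator --init uniform
thresholdpgg experiment --treatments all --pairs 14 --seed 1 --out-dir out/
```

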