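# pggnet

Critical synergy factors for the evolution of cooperation in **public
goods games (PGGs) on arbitrary networks** — weak-selection theory,
exact small-population oracles, exhaustive graph censuses, and
agent-based Monte-Carlo simulation.

## The problem

In a public goods game of group size *G*, cooperators contribute *c* to
a common pool; contributions are multiplied by a synergy factor *r* and
split evenly, so a cooperator earns `r·g_C·c/G − c` and a defector
`r·g_C·c/G` when *g_C* group members cooperate. On a network, every
agent *i* organizes one game among its group 𝒢ᵢ = {i} ∪ 𝒩ᵢ (size
Gᵢ = kᵢ + 1) and also plays in its neighbors' games; its payoff is the
average (or the sum) over those Gᵢ games. Strategies spread by
pairwise-comparison (PC), death-birth (DB), or birth-death (BD)
updating with fitness `exp(δ·payoff)` in the weak-selection regime
δ → 0.

Selection favors cooperation when the fixation probability of a single
uniformly placed mutant cooperator exceeds the neutral benchmark 1/N.
This happens precisely when the synergy factor exceeds a critical value
**r\***, a property of the network and the update rule. `pggnet`
computes r\* exactly (to solver precision) for any simple connected
unweighted graph, by reducing the first-order weak-selection condition
to linear functionals of pairwise coalescence times **τᵢⱼ** of two
coalescing random walkers:

```
τ_ij = 1 + (1/(2k_i)) Σ_{l∈𝒩_i} τ_lj + (1/(2k_j)) Σ_{l∈𝒩_j} τ_il ,   τ_ii = 0 .
```

Under PC the condition is `r > τ(1)/ϒ(1)` and under DB
`r > τ(2)/ϒ(2)`, where `τ(n) = Σ_{i,j} k_i p_ij⁽ⁿ⁾ τ_ij` weights
meeting times by the n-step random-walk kernel and ϒ is a group-size-
weighted combination of coalescence times assembled by
`upsilon_matrix`. BD and accumulated-payoff variants use the same
machinery with rule-specific edge weights and (for BD) the ancestral
chain of the BD process. The pairwise donation game (DG, benefit *b*,
cost *c*, threshold (b/c)\*) is included for comparison. Every
rule/game/payoff combination is validated against an exact 2^N
Markov-chain solve on all 141 connected graphs with N ≤ 6.

## Worked example

The star graph — one hub, n leaves — is hostile to cooperation in
pairwise games but supports it in PGGs at r\* = 4 under DB updating,
independent of size:

```python
import pggnet as pg

star = pg.make_star(9)                       # N = 10
res = pg.pgg_critical_r(star, rule="db")
print(res.value, res.category)               # 4.000000000000011 finite_supporting
print(pg.pgg_critical_r(star, rule="pc").value)   # 4.64285714285715
print(pg.dg_critical_bc(star, rule="db").category)  # no_support
```

The value 4.0 is the critical synergy factor: a single cooperator fixes
with probability above 1/10 whenever r > 4. Under PC the star needs
r > 4.64 at this size; the pairwise donation game on the star supports
no cooperation at all. The exact 2^N chain agrees:

```python
pg.oracle_critical(pg.make_star(5), rule="db").value   # 4.000000000030809
```

and Monte-Carlo simulation straddles the prediction (δ = 0.025, 10⁵
runs per point; the neutral benchmark is 1/N = 0.1):

```python
from pggnet.abm import SimConfig, estimate_cooperation
cfg = SimConfig(r=2.0, delta=0.025, rule="db", n_runs=100_000, seed=0)
print(estimate_cooperation(star, [2.0, 6.0, 10.0], cfg))
#    r  mean_rhoC   stderr  n_runs
#  2.0    0.09975 0.000948  100000
#  6.0    0.10009 0.000949  100000
# 10.0    0.10303 0.000961  100000
```

The same functions are exposed on the command line:

```
$ pggnet threshold --generator star --rule db -- 9
{"n_nodes": 10, "game": "pgg", "rule": "db", "payoff": "average",
 "value": 4.000000000000011, "category": "finite_supporting"}
$ pggnet census --sizes 3-6 --rule pc
$ pggnet simulate --generator lattice --rule db --r-grid 2:8:2 --runs 100000 -- 5
```

`pggnet fig2`, `fig3`, and `fig4` reproduce the synthetic-family
threshold table (with infinite-size extrapolations), the random-network
parameter sweeps, and the full 12,111-graph census report.

## Layout

- `pggnet.graphs` — network constructors (stars, joint stars, ceiling
  fans, periodic lattices, ER/WS/preferential-attachment ensembles) and
  edge-list I/O.
- `pggnet.coalescence` — random-walk kernels and the coalescence-time
  linear systems (sparse direct solve, with an exact automorphism-orbit
  reduction for large symmetric families).
- `pggnet.thresholds` — critical synergy factors and benefit-to-cost
  ratios for all rule/game/payoff combinations.
- `pggnet.census` — isomorph-free enumeration of connected graphs
  (N ≤ 8), classification and ranking.
- `pggnet.oracle` — exact fixation probabilities from the full 2^N
  Markov chain (ground truth for N ≤ 12).
- `pggnet.abm` — Monte-Carlo simulation (numba inner loops).
- `pggnet.experiments`, `pggnet.cli` — canned studies and the CLI.

See `docs/methods.md` for the model details, derivation route, and
numerical choices.
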