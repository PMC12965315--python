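# Methods

## Model

A population of N agents occupies the nodes of a simple, connected,
unweighted, undirected graph with adjacency k_ij, degrees k_i, neighbor
sets 𝒩_i, and groups 𝒢_i = {i} ∪ 𝒩_i of size G_i = k_i + 1. Each agent
i organizes one public goods game in 𝒢_i and participates in the games
of its neighbors. With binary strategies x_i ∈ {0, 1} (1 = cooperate)
the payoff of agent i is

    f_i(x) = (1/G_i) Σ_{l ∈ 𝒢_i} [ r c (Σ_{m ∈ 𝒢_l} x_m) / G_l − x_i c ]

under the *average* scheme; the *accumulated* scheme drops the 1/G_i
prefactor. The pairwise donation game (DG) replaces the group games by
one two-player game per edge: a cooperator pays c per game to deliver b
to the partner (averaged over the k_i games or accumulated).

Strategy dynamics are Moran-type elementary steps with fitness
F_i = exp(δ f_i), 0 < δ ≪ 1:

* **PC** — a uniform focal agent i picks a uniform neighbor j and adopts
  x_j with the Fermi probability 1/(1 + exp(−δ(f_j − f_i))).
* **DB** — a uniform agent i dies; its neighbors fill the vacancy
  proportionally to fitness. The focal agent's own payoff plays no role.
* **BD** — an agent reproduces proportionally to fitness in the whole
  population and its offspring replaces a uniform neighbor.

Cooperation is *favored* when the fixation probability of a single
cooperator placed uniformly at random exceeds 1/N. At first order in δ
this is equivalent to r > r\* (or b/c > (b/c)\*), the quantity this
package computes.

## Weak-selection condition

All thresholds come from one functional. Write the condition for each
rule as

    Σ_{i,j} W_ij · E[ (x_j − x_i) (f_j(x) − g_i(x)) ] > 0 ,

where W is a symmetric edge weighting, g_i is f_i (PC, BD) or the
neighbor-averaged payoff Σ_l p_il f_l (DB, because the dying agent's
payoff is irrelevant), and the expectation runs over the neutral
process summed along trajectories started from the uniform single
mutant. The ingredients are derived in two steps:

1. **Reproductive values.** v_i is fixed by requiring Σ_i v_i x_i to be
   a martingale of the neutral (δ = 0) chain: v_i ∝ k_i for PC and DB,
   v_i ∝ 1/k_i for BD. Weighting the first-order replacement
   probabilities by v gives W_ij = k_ij (PC, DB) and
   W_ij = k_ij/(k_i k_j) (BD).
2. **Pair correlations.** By the duality between the neutral forward
   dynamics and coalescing ancestral random walks, time-summed pair
   correlations from a uniformly placed mutant reduce to expected
   meeting times: E-sum[(x_j − x_i) x_m] ∝ τ_im − τ_jm. For PC and DB
   the ancestral chain is the standard voter-model pair walk (each of
   the two walkers moves with probability 1/2 per step). For BD the
   replacement rate is non-uniform — node i is replaced at rate
   d_i/N, d_i = Σ_l k_il/k_l — and, because the mutant is placed
   *uniformly*, the relevant quantity is the meeting time measured in
   elementary steps, i.e. the pair system with a constant source term.

Payoffs are linear in the state, f = Φx, so the condition is linear in
the game parameter θ (synergy factor r, or benefit b): it reads
θ·L_benefit > L_cost with both coefficients linear functionals of τ.
The threshold is the ratio L_cost/L_benefit. For PC and DB with average
PGG payoffs this reproduces the closed forms r\* = τ(1)/ϒ(1) and
τ(2)/ϒ(2), with ϒ the group-size-weighted coalescence combination
implemented in `upsilon_matrix` (the test suite asserts the identity on
a zoo of graphs).

**Validation.** The entire derivation is cross-checked against an
oracle that knows nothing of it: the exact 2^N-state Markov chain of
the full process, solved for fixation probabilities, with the critical
value located from the δ-derivative at δ = 0 (central differences at
δ = 1e-4 with a Richardson step at δ/2; the derivative is exactly
linear in θ, so two probes determine the root). Theory and oracle agree
to better than 1e-4 relative on all 141 connected graphs with N ≤ 6,
for all three rules, both games, and both payoff schemes; during
development an independent symbolic first-order solve of the 8-state
chain on the 3-path (r\* = 60/7 under PC) pinned down the same answer.

### Classification and sign conventions

Thresholds are categorized as *finite_supporting* (0 < r\* ≤ 30),
*strict* (30 < r\* ≤ 1000), or *no_support* (negative, beyond the
numeric-infinity cutoff 10³, or a condition whose payoff-gradient
coefficient L_benefit is negative so that no large parameter satisfies
it). When |L_benefit| < 1e-12·|L_cost| the ratio is numerically
meaningless and the graph is classified no_support (this is the
complete graph, where the functional vanishes identically). Populations
of N < 3 are rejected: with groups of two the PGG degenerates into a
rescaled pairwise game.

## Solving the coalescence systems

The pair systems have N(N−1)/2 unknowns and are solved by sparse LU.
Graphs with hubs make the LU fill in badly, so above 2,000 pair
unknowns the solver first attempts an exact symmetry reduction: the
automorphism group (BLISS generators, via igraph) partitions unordered
pairs into orbits on which τ is constant; the quotient system — often a
few dozen unknowns even for N = 400 lattices or double stars — is
solved densely and expanded. The reduction is exact and is tested
against the direct solve; graphs with trivial symmetry simply fall
back. Solution residuals are verified below 1e-10 in the maximum norm.

## Graph census

Connected graphs are enumerated one isomorphism class at a time by node
augmentation: every connected graph on n nodes contains a non-cut
vertex, so attaching a new node with every non-empty neighbor subset to
every class on n−1 nodes reaches all classes on n nodes. Duplicates are
removed by a canonical certificate (BLISS canonical permutation). The
counts — 2, 6, 21, 112, 853, 11,117 for N = 3…8, 12,111 in total —
match the known sequence, and N ≤ 5 is independently verified against
a labeled brute-force enumeration. Rankings sort ascending by
threshold, no-support classes last; ties (rare among 11,117 graphs)
share the minimal rank.

## Synthetic network families

Deterministic families (star, joint stars = a hub clique with private
leaves, ceiling fans = triangle blades on one hub, periodic von
Neumann / Moore lattices) are built exactly. Random ensembles follow
the standard constructions: G(N,p) rejection-sampled until connected
(preserving the conditional distribution; capped at 10,000 attempts);
Watts–Strogatz rings with 2d neighbors whose original clockwise edges
are each rewired once with probability p to a uniform non-neighbor,
rejection-sampled for connectivity; and Krapivsky-style growth in which
each newcomer attaches to m distinct nodes with probability ∝ k^γ.
Zero-degree nodes in the growth process get unit attachment weight —
the initialization leaves this open, and no quantitative result here
depends on the convention. Edge counts obey m(N−m) exactly, so the
mean degree is 2m(1−m/N).

Infinite-size values for the structured families are obtained from a
least-squares fit r\*(n) = a + b/n over a ladder of sizes (leaf counts
20–200, lattice sides 10–20); 1/n is the leading finite-size correction,
which the fit residual (< 0.01 for the fan families) confirms. The
reported large-size limits — star DB r\* = 4 at *every* size, ceiling
fans 21/4 (PC) and 27/8 (DB), joint stars 4m/(2m−1) under PC, Moore
lattice ≈ 5.8 under DB, and r\* → 1 for hub-connected double stars
under DB with accumulated payoffs — emerge from these fits.

## Agent-based simulation

The simulator implements the protocol exactly as specified by the
model: one uniformly placed cooperator, N elementary steps per
Monte-Carlo step (MCS), truncation at 4×10⁵ MCS with the current
cooperator fraction recorded (small populations essentially always fix
long before that), and averaging of the final ρ_C over independent
runs. Selection strengths 0.01–0.025 are numerically weak; c = 1.
Per-run seeds derive deterministically from a master seed
(`numpy.random.SeedSequence`), so campaigns are reproducible and
embarrassingly parallel. The numba kernel keeps the per-group
cooperator counts incrementally, so an elementary step touches at most
a second-order neighborhood; a pure-Python step implementation backs
the unit tests and is checked statistically against the kernel.

Replication is desk-scaled: 10⁵–10⁶ runs per parameter point rather
than 10⁶–10⁹. The star graph's per-run selection effect at δ = 0.025 is
only ~10⁻³ (computed exactly from the 2^10 chain), so the star
consistency check uses 10⁶ runs (≈10 s) while the 5×5 lattice, whose
effect is an order of magnitude larger, uses 10⁵. Flank tests at 95%
confidence (one-sided z) verify that the empirical crossing of
ρ_C = 1/N brackets the predicted r\*.

What the simulations do and do not show: they confirm the *sign* of
selection on specific graphs at small positive δ, with binomial
sampling error; they do not probe strong selection, mutation, or
non-single-mutant initial conditions, and agreement at δ ≤ 0.025 does
not guarantee accuracy of the weak-selection threshold at large δ.

## Known limitations

* Thresholds assume weak selection; the first-order condition can
  misorder networks at strong selection.
* Only unweighted, undirected, simple, connected graphs are supported.
* The exact oracle is limited to N ≤ 12 (2^N states); beyond that the
  theory is validated only by simulation.
* The orbit reduction helps only for graphs with substantial symmetry;
  asymmetric graphs above a few thousand nodes would need an iterative
  pair-system solver, which is not implemented.
* Empirical-network studies are supported through edge-list input but
  ship with no bundled datasets.
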