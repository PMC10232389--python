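# Methods

## Model and assumptions

The framework is a patch-dynamic (Levins-type) metacommunity model of a
food web on a large set of identical habitat patches. Each patch can hold
one subpopulation of each species; dispersal is global; a fraction
U ∈ [0, 1) of patches is permanently destroyed and unavailable for
colonization. The state of species *i* is its patch occupancy — no local
population sizes are tracked.

Assumptions, in the order they shape the equations:

* **Basal species exclude each other within a patch.** Competition acts
  through *displacement*: a colonizer of species *i* landing on a patch
  occupied by species *j* takes it over with probability `H[i, j]`. Hence
  the basal colonization term uses the vacant fraction `1 − U − Σ_j P_j`
  and the displacement term transfers occupancy between basal species in
  proportion to colonization pressure.
* **Consumers do not exclude each other.** A consumer's colonization is
  limited only by its own occupancy (`1 − U − A_i`) and is proportional to
  encounter with prey, `Σ_j θ_ji P_j + Σ_k δ_ki A_k`. One colonization rate
  per consumer regardless of which prey supports it.
* **Predation acts as extra extinction** (top-down rates μ on basal prey,
  φ on consumer prey), only across feeding links.
* **The predation graph is a DAG** — no loops, no cannibalism — with every
  consumer connected to at least one basal species through feeding paths.
  Consumer persistence is therefore bottom-up: without surviving prey a
  consumer's colonization term vanishes and it decays to extinction.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| `cP[i]` | basal colonization rate | evenly spaced on [0.45, 0.8] | 1/time |
| `eP[i]` | basal intrinsic extinction | 0.2 | 1/time |
| `cA[i]` | consumer colonization rate | 0.625 | 1/time |
| `eA[i]` | consumer intrinsic extinction | 0.05 | 1/time |
| `mu[i,k]`, `phi[i,k]` | top-down extinction on feeding links | 0.05 | 1/time |
| `U` | destroyed-patch fraction | 0 (swept 0–0.95) | — |
| `H[i,j]` | displacement probability | strict hierarchy | — |

The defaults are the standard parameterization of this model family: with
them a lone basal species at `c = 0.45` occupies `1 − e/c ≈ 0.56` of an
intact landscape, and consumers are fast colonizers (high `cA/eA`) whose
persistence is limited by prey availability rather than by their own
demography. The competition–colonization tradeoff is encoded by ordering:
species 1 is the top competitor and slowest colonizer, `cP` strictly
increasing with index. Two colonization ranges are used throughout — a
small one ([0.45, 0.8]) and a large one ([0.25, 1]) — because the width of
the range controls how much patch loss is needed before inferior
competitors can invade. "Irregular" spacing draws the rates i.i.d. uniform
from the range and sorts them (duplicates redrawn); equal rates (no
tradeoff) serve as the control in which oscillations must disappear.

## Competition structures

* **Strict hierarchy**: `H[i,j] = 1` for `i < j`, else 0. Relative
  intransitivity RI = 0.
* **Weakened hierarchy**: `H[i,j] = (1+w)/2` above the diagonal,
  `(1−w)/2` below; `w = 1` is the strict hierarchy, `w = 0` fair
  coin-flips. This one-parameter interpolation is this package's
  construction — the minimal way to soften the hierarchy continuously.
* **Intransitive tournaments**: 0/1 tournaments with cyclic dominance.
  RI is the cyclic-triad fraction: cyclic triads (computed from the score
  sequence, `C(n,3) − Σ_i C(s_i, 2)`) divided by the maximum attainable
  (`(n³−n)/24` odd n, `(n³−4n)/24` even n). RI = 0 for any transitive
  tournament, RI = 1 for rock–paper–scissors at n = 3. Tournaments with a
  target RI are built by randomized hill-climbing over single edge
  reversals starting from the hierarchy (sideways moves with probability
  0.1 to escape plateaus, 20 restarts); species labels — and hence the
  colonization ranking — are never permuted. A `rank_order` hook on the
  hierarchical constructor additionally allows competitive ranks to be
  decoupled from colonization ranks (local rather than global tradeoffs);
  it is exposed as a configuration option without claiming equivalence to
  any published variant.

## Steady-state protocol

The full system is integrated with adaptive RK45 (`scipy.solve_ivp`,
rtol 1e-8, atol 1e-10) for a burn-in of 15,000 time units, then averaged
over a further 5,000 units (trapezoidal rule on 1,001 even samples).
A species whose window mean falls below 1e-6 is flagged extinct and
reported at occupancy 0. The tight tolerances are needed because
occupancies near the extinction threshold must be resolved. Initial
conditions default to the uniform state `(1 − U)/(2S)`, which keeps the
basal guild inside its feasible simplex `Σ P_i ≤ 1 − U`; steady states are
insensitive to the start (verified in tests). Species are never removed
mid-integration — an occupancy of zero is absorbing in the equations —
and thresholding applies only to the window average. Window means more
negative than −1e-6 raise an error; smaller undershoot (integrator noise
around an extinct species) is clamped to 0.

**Stationarity extension.** The fixed 15,000-unit burn-in is sufficient
for typical configurations, but near a feasibility boundary (a species
whose equilibrium occupancy is ~1e-4) the slowest eigenmode can outlast
it: residual transients of order 1e-4 were observed against the exact
analytic equilibria. `run_to_steady_state(..., stationarity_tol=...)`
therefore optionally continues integration in 5,000-unit blocks (up to
60) until two successive window means agree within the tolerance in every
species. It is off by default; convergence-sensitive checks (analytic
cross-validation) switch it on with tol 1e-9.

## Analytic equilibria and community assembly

For μ = φ = 0 the basal block is exactly Lotka–Volterra,
`r_i = b_i + (M P)_i`, so a candidate equilibrium on any subset of
species solves a linear system. The surviving community is assembled
iteratively: solve on the current subset; while any occupancy is
non-positive, drop the most negative and re-solve; once strictly
positive, check every excluded species' invasion growth rate
`r_k = b_k + (M P*)_k` and reinstate the strongest invader if one is
positive. The accepted community is a *saturated* equilibrium — survivors
positive, excluded species unable to grow from rarity. The invasibility
step matters: pure most-negative removal can terminate on a non-maximal
community (observed on a random 6-basal web where the dynamics converge
to three basal survivors but removal alone kept two). Under a strict
hierarchy `M` is triangular in rank order, and the procedure reduces to
exact forward substitution: superior competitors are unaffected by
inferior ones. Survivors whose equilibrium lies below the extinction
threshold are zeroed without re-solving, mirroring the numerical
protocol. A singular restricted matrix (possible for degenerate rate
combinations) falls back to the ODE protocol with a warning.

Consumer equilibria are evaluated in one topological pass,
`A_i* = 1 − U − e_i^A / (c_i^A R_i)` with `R_i` the equilibrium prey
availability; a consumer with `R_i ≤ 0` or a non-positive solution is set
extinct before its own predators are evaluated.

## Complexity metrics

A *food chain* is a directed path from a top predator (a species nothing
feeds on) to a basal species; length is counted in links by default
(`fcl_convention="nodes"` counts species — both conventions appear in the
literature, and the switch is exposed because aggregate tables rarely say
which was used). Mean FCL averages over *all* such paths; max FCL is the
longest. Both are computed by a single topological-order pass
accumulating path counts, length sums and maxima per species — exact and
linear in edges — while `food_chains` enumerates paths explicitly and
serves as the independent oracle in tests. An isolated basal species (no
predators) counts as a degenerate length-0 chain; this arises only in
heavily pruned realized webs. An *omnivore* has ≥ 2 prey and basal-rooted
feeding paths of ≥ 2 distinct lengths (it feeds on more than one trophic
level); path-length *sets* are propagated up the DAG. Connectance is
`2L/[S(S−1)]`, undefined (NaN) below two species. Basal diversity is the
inverse Simpson index `1/Σ q_i²` on relative abundances
`q_i = P_i / Σ_j P_j`.

The *realized* web at a steady state is the induced subgraph on
non-extinct species, with consumers that retain no surviving prey removed
in cascade (one topological pass).

## Patch-loss sweeps

The default gradient is U = 0 to 0.95 in steps of 0.005 — fine enough to
resolve the narrow coexistence bands in which an inferior competitor
persists. For predation-free configurations the analytic equilibria are
used at every level (the `auto` method), with optional cross-validation:
k randomly chosen levels re-solved by the ODE protocol and the largest
occupancy discrepancy recorded in the result. Turning points are census
events — a basal species' steady-state occupancy crossing the extinction
threshold between adjacent grid points, labelled enter or leave. The
oscillation statistic is the count of local maxima of the
inverse-Simpson-vs-U profile after an edge-preserving width-3 median
filter (plateaus count once, boundary points count when they exceed their
inner neighbour, gaps where the guild is extinct count as 0). This
statistic is this package's operationalization of "oscillations" — output
manifests label it as such — since no standard numerical definition
exists.

## Synthetic webs

Random webs emulate the aggregate structure of empirical island food webs
(S, basal count, L; acyclic; no cannibalism; every consumer basal-rooted)
via a layered construction: each consumer draws a trophic layer (1 to
min(n_A, 4)), receives one mandatory prey link from a strictly lower
layer (basal = layer 0), and the remaining links are placed uniformly at
random among unused lower-layer pairs. Layer draws are rejected (up to
200 times, then replaced by an all-distinct layering) if they cannot host
the requested L. The construction guarantees the DAG and reachability
invariants by induction on layers and produces chains of unequal length,
hence omnivores. It does **not** reproduce empirical degree
distributions, niche-model interval structure, or the particular
adjacency matrices of any published web — so sweep results on synthetic
webs reproduce the *qualitative* phenomena (non-monotone complexity,
oscillating basal diversity, turning points) rather than any published
curve, and passing tests should be read accordingly.

## Problem sizes and numerical choices in the test suite

Tests and the acceptance script run at the scale of the empirical
templates: webs up to S = 28, basal guilds up to n_P = 6, sweeps on the
191-point default grid, 50 random webs for the analytic-vs-ODE
comparison, and 10 seeds for the oscillation experiment — sizes chosen to
match the phenomena's natural scale while keeping the full suite at
about a minute. The basal-only oscillation experiments are deterministic
given even colonization spacing; seeds there drive the random choice of
cross-validation levels (and irregular-spacing draws where used).

Known limitations: no stochastic (finite-patch) simulation, no explicit
spatial geometry, no transient analysis, no formal stability analysis of
the full web with predation (the analytic route requires μ = φ = 0); the
hill-climbing tournament search is heuristic and reports the best RI
found when a target is unreachable; and the weakened-hierarchy
interpolation and local-tradeoff rank permutation are this package's own
constructions for exploring robustness, not reproductions of any
published variant.
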