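# webpatch

Patch-dynamic metacommunity models of complex food webs under habitat loss.

`webpatch` is for theoretical ecologists studying how habitat destruction
reshapes trophic communities. It implements a Levins-type patch-occupancy
framework for whole food webs: basal species compete for patches through
competitive displacement under a competition–colonization (C–C) tradeoff,
consumers persist bottom-up on the occupancies of their prey, and a fraction
*U* of patches is permanently destroyed. Sweeping *U* traces how species
richness, food-chain length, omnivory and basal diversity respond to habitat
loss — and shows that the response is not a simple monotone decline:
diversity and food-web complexity rise and fall repeatedly along the
gradient, driven by basal species entering and leaving the community at
"turning points".

## Model

State variables are patch occupancies (fractions of patches occupied).
Basal species *i* follows

```
dP_i/dt = c_i^P P_i (1 − U − Σ_j P_j)            colonization
          − e_i^P P_i                             extinction
          + Σ_j (c_i^P P_i H_ij P_j − c_j^P P_j H_ji P_i)   displacement
          − P_i Σ_k θ_ik μ_ik A_k                 top-down predation
```

where `H_ij` is the probability that a colonizer of species *i* displaces a
resident of species *j* (strict hierarchy: `H_ij = 1` for `i < j`), and
`θ_ik = 1` if consumer *k* feeds on basal species *i*. Consumer *i* follows

```
dA_i/dt = c_i^A A_i (Σ_j θ_ji P_j + Σ_k δ_ki A_k)(1 − U − A_i)
          − e_i^A A_i − A_i Σ_k φ_ik δ_ik A_k
```

The C–C tradeoff assigns strictly increasing colonization rates to
decreasing competitive rank: species 1 is the best competitor and the
slowest colonizer. Without top-down predation (μ = 0) the basal guild has
Lotka–Volterra per-capita form `r_i = b_i + Σ_j M_ij P_j` with
`b_i = c_i^P(1 − U) − e_i^P` and `M_ij = c_i^P H_ij − c_j^P H_ji − c_i^P`,
so the surviving community and its equilibrium `P* = −M⁻¹ b` can be found
exactly; consumer equilibria
`A_i* = 1 − U − e_i^A / (c_i^A · prey availability)` then follow in
prey-before-predator order because the predation graph is acyclic.

Because empirical island webs are rarely published as adjacency lists, the
package generates random layered-DAG webs matching their aggregate structure
(species count S, basal count, link count L); the four classic island webs
used as size templates have S = 14, 15, 24, 28 with connectance
`C = 2L/[S(S−1)]` = 0.25, 0.24, 0.12, 0.15.

## Worked example

```python
from webpatch import PatchOccupancyModel, assign_cc_tradeoff, generate_web

web = generate_web(n_P=3, n_A=11, L=23, seed=7)   # S=14, C≈0.25 size class
model = PatchOccupancyModel(web)   # strict hierarchy + C–C tradeoff defaults
print(model.fit().summary())
```

```
Patch-occupancy steady state
==============================================
method:            ode
patch loss U:      0.000
competition:       hierarchical
species (potential): 14  (basal 3, consumers 11)
species (surviving): 10
links (realized):  11
connectance:       0.2444
mean / max FCL:    1.667 / 2
omnivory:          0.100
basal inv. Simpson: 1.874
----------------------------------------------
species_id     role  occupancy  extinct
        P1    basal   0.348771    False
        P2    basal   0.000000     True
        P3    basal   0.205046    False
        A1 consumer   0.695966    False
...
```

Ten of fourteen species persist without habitat loss; the mid-ranked basal
species P2 is competitively excluded, and four consumers fall with it. The
patch-loss gradient experiment on the basal subsystem (top-down effects
switched off, `μ = 0`) shows the oscillating diversity profile:

```python
params = assign_cc_tradeoff(web, mu=0.0, phi=0.0)
sweep = PatchOccupancyModel(web, params=params).sweep(mode="basal_only",
                                                      cross_validate=5, seed=0)
print(sweep.n_diversity_peaks(), len(sweep.turning_points()))
for e in sweep.turning_points():
    print(f"  {e.species} {e.direction}s between U={e.U_lo:.3f} and {e.U_hi:.3f}")
```

```
2 7
  P3 enters between U=0.205 and 0.210
  P2 enters between U=0.380 and 0.385
  P3 leaves between U=0.515 and 0.520
  P1 leaves between U=0.555 and 0.560
  P3 enters between U=0.590 and 0.595
  P2 leaves between U=0.675 and 0.680
  P3 leaves between U=0.745 and 0.750
```

The basal inverse-Simpson profile has two local maxima, and its global
maximum sits at U = 0.47 — an intermediate level of habitat destruction,
not the pristine landscape. Fast colonizers that are poor competitors enter
the community only once destruction has knocked back their superiors, then
leave again as destruction proceeds; each crossing is a turning point, and
the alternation produces the zig-zag diversity profile.

The same experiments are available from the shell:

```sh
webpatch generate --n-basal 3 --n-consumers 11 --links 23 --seed 7 --out web.tsv
webpatch metrics --web web.tsv
webpatch sweep --config run.yaml --out sweep.csv   # + JSON run manifest
```

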