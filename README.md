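# consnet

**When is it worth mapping the social network before planning conservation
interventions?**

`consnet` is a decision-analysis toolkit for conservation planning on
social networks. Each node of a network is a social actor (a landholder, a
fisher group, ...) with exclusive management rights over one
species-bearing site; sites are *available*, *developed* or *reserved*
(the latter two absorbing), and behaviour spreads between connected actors
by an independent-cascade process. A planner targets one actor per time
step with an intervention that enables the reserve transition, aiming to
maximize the discounted number of species represented in reserves. The
package provides:

* the per-node stochastic kernel and synchronous network dynamics
  (`consnet.dynamics`) — an available actor develops with hazard
  `1 − (1−p_d)·Π(1−u_d,ij)` over developed neighbours, and (only when
  targeted) reserves with the analogous `p_r`/`u_r` hazard;
* an exact factored-MDP planner (`consnet.planner`): value iteration over
  all `3^n` joint states, greedy policy extraction, exact policy
  evaluation by sparse linear solve;
* species-by-site incidence matrices with controlled nestedness, the
  Brualdi–Sanderson discrepancy index and a fixed-marginals permutation
  test (`consnet.species`);
* the five canonical 6-node motifs (ring, line, ring-star, wheel, star)
  spanning a gradient of Freeman closeness centralization
  (`consnet.networks`);
* value-of-information analysis (`consnet.experiments`): the percent
  improvement from planning with the true network versus planning as if
  actors were unconnected, both policies evaluated exactly under the true
  dynamics —
  `VoI% = 100·(V_informed − V_blind)/V_blind`;
* file formats, YAML-configured CLI and a synthetic small-scale-fishery
  case study (`consnet.io`, `consnet.cli`).

It is aimed at conservation decision scientists and quantitative ecologists
studying when social data collection pays off, and at anyone needing a
small, exact, well-tested network-intervention MDP.

## Worked example

```python
import numpy as np
import consnet as cn

# a 6-node star with strong influence links, and a species pool of 20
# drawn toward the un-nested end of the nestedness scale
rng = np.random.default_rng(3)
species = cn.generate_species_distribution(n_species=20, n_sites=6,
                                           phi=0.1, rng=rng)
net = cn.build_motif(cn.MotifSpec("star"), u_r=1.0, u_d=1.0)
model = cn.DecisionModel(network=net, species=species,
                         params=cn.BehaviorParams(p_d=0.2, p_r=0.2))
res = cn.compute_voi(model)
print(f"nestedness score : {species.score:.3f}")
print(f"site richness    : {species.site_richness}")
print(f"V informed       : {res.v_informed:.2f}")
print(f"V network-blind  : {res.v_uninformed:.2f}")
print(f"VoI              : {res.voi_percent:.2f}%")
print(f"first action     : informed -> node {res.first_action_informed - 1}, "
      f"blind -> node {res.first_action_uninformed - 1}")
```

prints

```
nestedness score : 0.625
site richness    : [ 7 10  9 12 12  6]
V informed       : 137.06
V network-blind  : 113.41
VoI              : 20.85%
first action     : informed -> node 0, blind -> node 4
```

The network-blind planner starts at a most species-rich site (node 4,
richness 12). The informed planner instead starts at the hub (node 0,
richness 7): once the hub is reserved, every later leaf intervention
succeeds with near-certainty through the `u_r = 1` links, and the reserved
hub can never spread development. Knowing the network is worth a 20.9%
improvement in expected species representation here. With `u_r = u_d = 0`
the two planners coincide and the VoI is exactly 0; with a perfectly
nested pool (`phi = 1.0`) a couple of rich sites capture every species and
the VoI collapses toward 0 whatever the network looks like.

The same analysis runs from the shell:

```bash
consnet voi --config cfg.yaml --outdir out/        # one instance
consnet grid --config cfg.yaml --outdir out/       # full factorial study
consnet casestudy --config cfg.yaml --outdir out/  # fishery-like fixture
consnet solve --config cfg.yaml --outdir out/      # policy/value export
```

Each command writes a resolved copy of its configuration next to its
outputs; `grid` emits tidy per-instance records and a per-motif summary
(mean VoI with bootstrap interval, first-action fractions, tercile
breakdowns).

## File formats

* **Edge list CSV** — header `source,target,u_r,u_d`; 0-based node ids,
  one row per undirected link.
* **Incidence CSV** — rows = sites, columns = species, 0/1 entries,
  header row of species names.
* **Config YAML** — mirrors `consnet.io.RunConfig` (motif or CSV inputs,
  behaviour parameters `p_d, p_r`, link strengths, discount, intervention
  cost, grid axes, master seed).

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.

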