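# Methods

## The decision problem

`consnet` models a conservation planner choosing, at each discrete time
step, a single social actor to target with an intervention (a payment,
purchase, or co-management agreement) on a network of `n` actors who each
hold exclusive rights over one species-bearing site. Each actor/site is in
one of three states — **available (A)**, **developed (D)** or **reserved
(R)** — with D and R absorbing. Species persist at available and reserved
sites and are lost from developed ones; only reserved sites count toward
the objective.

The planner maximizes the expected infinite-horizon discounted sum of the
number of species represented in at least one reserved site, minus a
notional cost `c` per intervention:

    V*(s) = max_a  E[ Σ_t γ^t ( rep(s_t) − c·1{a_t ≠ no-op} ) ]

where `rep(s)` counts species with ≥ 1 presence at a reserved site of `s`.

## Behaviour spread

Transitions follow an independent-cascade / susceptible–infected scheme.
An available actor `i` develops in one step with hazard

    q_d,i = 1 − (1 − p_d) · Π_{j ∈ N(i), s_j = D} (1 − u_d,ij)

combining an intrinsic propensity `p_d` with the influence `u_d,ij` of each
already-developed neighbour as independent triggers. Reservation is
possible only for the actor targeted by the intervention that step, with
the analogous hazard `q_r,i` built from `p_r` and reserved neighbours'
`u_r,ij`; without an intervention `p_r` and `u_r` are inactive. With
homogeneous strengths the products collapse to `(1−u_d)^{n_d}` and
`(1−u_r)^{n_r}`.

When both latent events fire in an intervened step, the **reserve event
takes precedence**: `P(A→R) = q_r`, `P(A→D) = (1−q_r)q_d`,
`P(A→A) = (1−q_r)(1−q_d)`. The rule is isolated in
`dynamics.node_transition_distribution`; the alternative (normalizing the
two hazards) differs only at order `q_r·q_d` and does not change the
qualitative results. Updates are synchronous: every node's kernel is
conditioned on the same pre-step joint state, as is standard in cascade
models.

## Exact planning

The joint kernel factorizes over nodes, so per-action transition matrices
on the `3^n` encoded states (base-3, node 0 least significant) are
assembled as elementwise products of per-node factor matrices and stored
sparse. Value iteration runs to a sup-norm Bellman residual of `1e-6`
(geometric contraction at rate γ); greedy extraction breaks ties toward
no-op and then the lowest node index; policies are valued exactly by
solving the linear system `(I − γ P_π)V = R_π`. Reward is accrued on the
pre-transition state, so the initial all-available step contributes 0.
Exact planning is exponential in `n`; networks beyond 8 nodes are refused
rather than approximated.

Defaults: `γ = 0.95` (a planning horizon of ~20 effective steps, long
relative to the ~5 steps in which unmanaged development saturates a 6-node
network) and `c = 0.1` species-units (small enough that intervening is
almost always worthwhile, large enough to break no-op ties). Both are
config-exposed.

## Species distributions and nestedness

Species occupancy is generated per species with range size uniform on
`{1..n_sites}` (the field's default uninformative choice for a small site
pool). Nestedness is measured by the Brualdi–Sanderson discrepancy `d`:
after ordering sites by decreasing richness and species by decreasing
incidence (ties broken by original index; no search over orderings), `d`
counts presences outside the maximally packed matrix with the same row
sums. The normalized score `φ̂ = 1 − d/F` (`F` = total presences) maps
`d` to `[0, 1]` with 1 = perfectly nested.

The generator starts perfectly nested (score 1), then applies range-size-
preserving single-presence moves, accepting moves that do not increase the
distance to the target `φ` (plateau moves allowed; 500 proposals without
strict improvement, or 10,000 total, stop the walk; tolerance 0.02).
Finally the site rows are randomly permuted so that richness rank is
independent of node position — without this, the nested construction would
always place the richest site at the motif hub and the value of network
information would be artificially erased. The permutation preserves range
sizes; the score is recomputed afterwards because index tie-breaking is
ordering sensitive.

**Feasibility bound.** For 20 species × 6 sites with uniform range sizes,
the maximum achievable discrepancy is ≈ 17–20, so the score cannot fall
below ≈ 0.65–0.8; long simulated-annealing maximization of `d` reaches the
same floor as the production walk. Low `φ` targets therefore yield the
*most anti-nested matrices this normalization admits*, flagged
`converged=False`. Consequences for the study are discussed under
*Limitations*.

Significance is assessed against a fixed-marginals null generated by
sequential 2×2 checkerboard swaps (burn-in 5× the thinning interval,
thinning `max(2F, 100)` attempted swaps), with
`p = (1 + #{d_null ≤ d_obs}) / (n_perm + 1)`. A perfectly nested matrix
admits no checkerboard (its site supports form an inclusion chain), is
therefore the unique matrix with its marginals, and reports a degenerate
null with `p = 1`.

## Value of network information

For one instance, the informed planner solves the true model; the
network-blind planner solves the same model with every link strength set
to zero (actors assumed independent) — its optimal strategy is to work
through sites in order of species richness. Both policies are then valued
**exactly under the true dynamics** from the all-available state, and

    VoI% = 100 · (V_informed − V_blind) / V_blind .

Because the informed greedy policy is optimal under the true model, VoI is
nonnegative up to solver tolerance. Per-instance VoI is deterministic;
randomness enters only through the replicate species draws.

The grid runner sweeps motif × φ × u_r × u_d × replicate. Species draws
are seeded per (φ, replicate) and shared across strength cells and motifs
(common random numbers, paired comparisons); the blind policy is cached
per species draw and transition matrices per (motif, u_r, u_d).
Summaries report per-motif means with percentile-bootstrap 95% intervals,
first-action fractions (richest-site and most-central-node targeting,
ties counting as satisfied), and conditional means by rank-based terciles
of φ and mean link strength — deliberately plain empirical statistics
rather than a mixed-model fit.

## Motif topologies

Edge sets live in one table (`networks.motif_edges`), node 0 the hub where
one exists: ring = n-cycle; line = path; star = hub + leaves; wheel = hub
+ rim cycle + spokes; ring_star = n-cycle plus chords from node 0 to the
two nodes two steps away, making node 0 a partial hub. The ring_star
choice places its Freeman closeness centralization (0.388 at n = 6)
strictly between the line (0.291) and the wheel (0.643), preserving the
intended centralization gradient ring < line < ring_star < wheel < star
while the wheel keeps the strictly highest density. (A rim-cycle-plus-hub
variant touching only two rim nodes was rejected: its centralization,
0.223, falls below the line's and breaks the gradient.)

Closeness uses unweighted hop distances even on weighted networks (one
centralization per topology); a node in a component of size `k` has
closeness `(k−1)/Σd`, an isolated node 0, and centralization normalizes by
the star's value `(n−1)(n−2)/(2n−3)`.

## Synthetic fishery case study

`io.make_fishery_fixture` builds a 6-node stand-in for a small-scale
gear-group fishery: labelled nodes (speargun, handline, seine net, ring
net, gillnet, other), exactly one isolated node (speargun), density 0.4,
heterogeneous seeded link strengths with the handline–seine link
strongest, and a species distribution drawn to be indistinguishable from
random under the permutation null (p > 0.1) with the seine-net site
strictly richest. It reproduces qualitative structure, not real survey
data. On this fixture both the informed and blind planners target the
seine-net group first and VoI is a few percent.

## What the synthetic data do and do not emulate

The generator reproduces: controlled nestedness gradients at fixed range
sizes, random placement of richness relative to network position, and
replicate-to-replicate variability. It does not emulate: spatial
autocorrelation of ranges, abundance (presence only), actor heterogeneity
in `p_d`/`p_r`, or empirically calibrated link strengths. Passing tests
therefore demonstrate correctness of the planner and the comparative
statics of network structure/nestedness, not predictive accuracy for any
real landscape.

## Numerical choices

Value-iteration tolerance `1e-6` (sup-norm residual); policy evaluation by
direct sparse solve; greedy tie tolerance `1e-9` toward no-op/lowest
index; VoI reported as exactly 0 when both values vanish, and as a flagged
absolute difference if the blind value is nonpositive while the informed
value is positive (never observed on the study grids); state encoding
validated by exhaustive round-trip. Desk-scale study runs use
φ {0.1, 0.4, 0.7, 1.0} × u {0.0, 0.2, ..., 1.0}² × 5 replicates per motif
(a uniform subsample of the full 10 × 11 × 11 × 5 factorial keeping every
axis endpoint), solving ~3,600 exact MDP instances in a few minutes.

## Known limitations

* The `1 − d/F` nestedness score compresses the anti-nested end: for this
  matrix shape it cannot reach targets below ≈ 0.65, so the "un-nested"
  regime is the most anti-nested *achievable* rather than a literal score
  of 0.1. VoI in that regime (star motif, strong links: ≈ 10% on the desk
  grid) is correspondingly attenuated relative to analyses whose
  un-nested matrices are more extreme; the comparative ordering across
  motifs and nestedness levels is unaffected.
* Exact planning stops at 8 nodes by design; approximate dynamic
  programming for larger networks is out of scope.
* The blind baseline ignores links at planning time but is evaluated under
  true dynamics; a baseline blind at evaluation time too would answer a
  different (counterfactual-dynamics) question.
* Discrepancy uses one deterministic ordering; implementations that
  optimize over column orders can report slightly smaller `d` on tied
  marginals.
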