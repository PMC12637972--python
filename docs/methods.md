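# Methods

## The model

`stemcomp` simulates a fixed-size pool of stem cells under chronic
irradiation. Two types exist: intact and damaged. Radiation converts
intact cells to damaged irreversibly; any repair is folded into the
per-hit damage probability. Competition follows a Moran process in which
division is uniform but elimination is cost-weighted, and the cost of a
cell is the expected cost of a pairwise interaction with a random partner
(well-mixed) or the average over its 8 Moore neighbours (lattice). Cost is
inverse fitness: a common positive rescaling of all four matrix entries
leaves the process law unchanged, since costs enter the transition
probabilities only as ratios. The model therefore has three effective
inputs: the cost matrix up to scale, the pool size `N` (or lattice side
`L`, `N = L²`), and the dose-rate parameter `λ`.

Time is measured in cell cycles; one cycle is `N` elementary steps, each
consisting of a radiation sub-event followed by a division/elimination
sub-event. Costs are evaluated *after* the radiation sub-event of the same
step, i.e. a cell damaged this step competes as damaged immediately.

## Radiation scheme

`λ` is simultaneously (a) the expected number of conversions per
elementary step in a mostly intact pool and (b) the expected number of
hits per cell per cell cycle. Both readings are honoured by giving each
intact cell an independent conversion probability `1 − exp(−λ/N)` per
elementary step (Poisson thinning): summed over a mostly intact pool the
per-step expectation approaches `λ`, and accumulated over the `N` steps of
a cycle the per-cell hit count is `λ`. Unlike a single-hit Bernoulli
scheme this is well defined for every `λ ≥ 0`.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `c_ii, c_id, c_di, c_dd` | pairwise interaction costs (dimensionless) | — | user input; benchmark sets: neutral `(1,1,1,1)`, damage-advantaged `(1,1,0.8,0.8)`, damage-disadvantaged `(1,1,1.25,1.25)`, coordination `(1,1.5,1.16,0.8)` |
| `lam` | damaging hits / cell / cell cycle | — | occupational benchmark: 0.08 (0.01 mGy/h, 8 h day, 1 mGy per track, H = 1) |
| `n`, `side` | pool size / lattice side | 20 / squares in 16–100 | dose sweeps use N = 20; lattice comparisons need integral sides |
| `max_cycles` | censoring cap | `1e7 / N` cycles | damage-disadvantaged regimes at tiny λ are astronomically slow; a censored record beats a silent hang |
| `reps` | replicates per condition | 1000 (dose sweep), 50 (lattice comparison) | 50 replicates suffice for stable means; 1000 gives smooth dose–response curves |
| shape grid | pool sizes for shape classification | 2…1e5, log-ish | resolves both the small-N dip and the large-N recovery of convex-down regimes |

## Numerical choices

* **Fixation probability.** `π₁ = 1/(1 + Σ_j Π_k G_k/F_k)` is evaluated as
  a log-sum-exp over cumulative sums of `log(G_k/F_k)`. Direct products
  overflow doubles near `N ≈ 10³–10⁴` in dominance regimes; the log path
  is exact-to-rounding up to `N = 10⁵` and beyond. A dense
  hitting-probability linear solve provides an independent second route
  (tested to 1e−10 agreement on random matrices, `N ≤ 50`).
* **Exact absorption time.** For `N ≤ 100` the composite one-step kernel
  (binomial radiation jump, then tridiagonal Moran step) is built
  explicitly and `(I − Q)t = 1` solved. This is the oracle the stochastic
  engine is validated against; a sympy symbolic solve of the 3-state
  `N = 2` chain validates the construction itself.
* **Shape classification.** Successive differences of `log f(n)` are
  thresholded at a relative tolerance of 1e−9: the neutral matrix must
  classify as constant rather than noise-monotone, while genuine
  selection signals are many orders of magnitude larger. Convex-down
  requires exactly one sign change (fall then rise); anything mixed is
  reported as `other` rather than forced into a category. The two
  boundary indicators — `f(3) < f(2)` and `f(10⁵) > f(5·10⁴)` — are
  computed numerically from the same log-space evaluator with strict
  inequalities.
* **Lock-step batch engine.** Replicate sweeps advance all trajectories
  together through vectorised binomial and uniform draws, dropping
  finished replicates. This draws from one stream per condition instead
  of one per replicate; the law is identical and conditions remain
  independently seeded via spawned `SeedSequence` children.
* **Lattice cost updates.** After a flip only the site and its 8
  neighbours change cost, so the simulator patches the cost field locally;
  a full-recompute reference path exists and the suite checks the two
  produce identical trajectories under a shared random stream.
* **Degenerate inputs.** `k = 0` and `k = N` are fixed points of the
  competition step; `λ = 0` with an all-intact start is rejected (the
  target state is unreachable); `L = 3` lattices are allowed but logged as
  degenerate (every site neighbours every other); non-square pool sizes
  are rejected by the lattice comparison runner rather than approximated.

## Design choices where the design was open

* **Replacement rule.** The eliminated site is refilled by a uniform draw
  from a 9-candidate set: the removed cell's former occupant plus its 8
  neighbours. Including the removed cell itself is the only reading under
  which the removed type can reappear in place, and it makes a uniform
  grid an exact fixed point.
* **Lattice comparison point for negative frequency dependence.** Under a
  hawk–dove matrix the damaged count has a quasi-stable interior
  equilibrium, and at any finite `λ` the mean absorption time is dominated
  by the dwell near coexistence rather than by the waiting time for a
  successful invasion (for `(1, 0.25, 0.5, 0.75)` at `N = 36`,
  `λ = 0.002` the exact well-mixed mean is ≈ 14 500 cycles against a
  low-dose prediction of ≈ 331). The lattice-versus-well-mixed contrast is
  therefore assessed by direct simulation at `N = 36`, `λ = 0.002`, where
  the spatial clustering effect (damaged clusters shield their members
  from cross-type elimination) separates the two models by an order of
  magnitude. At `N = 16` and this `λ` the finite-`λ` dwell reverses the
  naive comparison — a reminder that "low dose rate" is matrix- and
  size-dependent.
* **Finer analytic grid for the convex-down contrast.** For
  `(1, 1.75, 1.25, 0.5)` the analytic curve's minimum sits at `n ≈ 20`;
  a four-point grid `{16, 36, 64, 100}` cannot resolve the dip, so the
  shape over that range is classified on a nine-point grid spanning the
  same interval. The lattice simulation itself runs at the four perfect
  squares.
* **Default `λ = 0.002` for lattice comparisons.** Small enough that the
  qualitative spatial contrasts manifest, large enough that 50–100
  replicates complete in minutes on one core.

## What the simulations do and do not show

The experiment sweeps generate all data internally from the model itself;
there is no external data. Passing tests show that the implementation is
internally consistent (simulation matches exact chain algebra, two
independent fixation-probability routes agree, lattice and well-mixed
coincide in the neutral case) and that the qualitative claims hold at the
stated parameter points. They do not show anything about real tissue:
the model has exchangeable cells with a single scalar cost, no repair, no
influx of fresh stem cells, no dose-rate dependence of the cost entries,
and a torus topology with exactly eight neighbours. Fixation-time
statistics beyond the mean, coexistence behaviour at high dose rates, and
non-square or three-dimensional geometries are out of scope.

## Problem sizes

Replicate counts and grids used by the test suite: 2000 replicates for
simulation-versus-exact checks at `N ∈ {2, 5, 10}`; 5000 fixation
replicates at `L = 5`; 100 replicates per condition for the lattice
contrasts at `N ∈ {16, 36, 64, 100}`; a 20×20 shape diagram over
`(c_di, c_dd) ∈ [0.5, 1.5]²`. These sizes give 3-standard-error
resolution on every comparison the suite makes.
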