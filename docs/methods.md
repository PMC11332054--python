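# Methods notes

## Model and assumptions

A matrix community model couples `S` single-species stage-structured
projection models through one scalar state: the aggregate resource load
`N(t) = Σ_j Σ_i w_ij n_ij(t)`, where `w_ij` is the resource footprint
(space, biomass) of one stage-`i` individual of species `j`. The model is
*interaction neutral*: no pairwise coefficients exist; all interspecific
effects are mediated by `N` against a community carrying capacity `K`.
Abundances are continuous nonnegative reals — the stochasticity is
environmental (year-type draws), not demographic; integer sampling noise is
out of scope.

**Within-step order (lag-1 density dependence).** Each step: (1) read the
year type, (2) compute `N` from the current census `n(t)`, (3) apply the
dependency assumption, (4) project every species one step, (5) apply the
extinction threshold. Density dependence therefore acts with a one-step
lag, matching a discrete annual census. The alternative (load recomputed
mid-step from survivors) is not implemented; with the lag-1 convention the
space ceiling still guarantees `N ≤ K` whenever survival transitions cannot
expand a cohort's footprint (see *fixtures* below).

**Dependency modes.**

* *Space-limited recruitment* (ceiling): open space `max(0, K − N)` caps
  the total footprint of new stage-1 recruits. Demand is either
  adult-driven (the `F` row of the matrix applied to `n(t)`) or, with the
  rescue effect, equal to the full open space for any species with positive
  abundance in a year type where it can establish
  (`SpeciesModel.recruitment_years`). Contested space is split
  proportionally to demand by default; equal-share and priority rules are
  selectable. Proportional allocation is the default because it is neutral
  and permutation-equivariant — relabeling species permutes trajectories
  exactly.
* *Biomass-limited fecundity / generic scaling* (multiplicative): every
  entry with the target role (default `F`) is multiplied by
  `max(0, 1 − N/K)`; the multiplier is clamped to `[0, 1]`, reaching 0 at
  `N = K`. Any callable `(N, K) → [0, 1]` can be substituted, so other
  published regulation forms can be matched when their equations are in
  hand. `K = 0` is allowed and means total suppression of the regulated
  rates.

**Exactness of the decoupled limit.** When the dependency is disabled (or
its multiplier is exactly 1, or the recruitment cap is not binding) the
community step reuses the identical matrix–vector product as the
single-species path, so the decoupled community equals independent
projections *bitwise*, not just to tolerance. This is a deliberate
implementation invariant, used as a regression oracle.

**Extinction.** A species whose total abundance falls below the
`extinction_threshold` (strictly; default 0, i.e. only exact zero) is set
to zero with an event logged, and stays extinct — the rescue effect
requires positive abundance. A threshold of ~1 individual reproduces the
quickened extirpation of small populations under adult-driven fecundity.

## Randomness

One root seed; every stochastic operation draws a named substream
(`rng_stream(seed, *tags)`, a `SeedSequence` spawn-key construction that is
stable across platforms). Sensitivity replicates use **common random
numbers** by default: replicate `r` sees the same year-type sequence at
every grid value, so grid contrasts are not diluted by environmental noise
and a degenerate one-point grid reproduces the baseline run bit-for-bit.
Independent per-(grid, replicate) streams (`common_random_numbers=False`)
are used when the replicate noise itself must be independent across grid
values, e.g. when auditing the size of the retention test.

## Growth rates

`asymptotic_growth_rate` returns the spectral radius and the unit-sum
nonnegative right eigenvector; reducible or periodic matrices yield a
warning and one valid choice. `stochastic_growth_rate` estimates
`log λ_s` as the average one-step log growth of total abundance over
replicates, with per-step renormalisation (no overflow at any horizon) and
a burn-in of 10% of the horizon discarded by default — the transient is
unspecified in general, and 10% removes it at every fixture's spectral gap.
Paths hitting exact zero contribute −∞ and are excluded from the mean but
counted and reported.

## Sensitivity protocol

Targets are addressed as `(species, 1-based row, 1-based column)` plus an
optional year-type set (default: all year types, requiring the entry to be
identical across them) and a parameterization: `rate` (the grid moves the
entry) or `mortality` (the grid moves `m`, entry `= 1 − m`) — both views of
the same entry are exposed because survival-class perturbations are
conventionally reported as mortalities.

Defaults follow the standard protocol: grid = actual value ± 0.10 in steps
of 0.01 (21 points), clipped to `[0, 1]` for probability-class entries;
up to 1000 replicates per grid value, run in batches of 100 with an early
stop once the running means move < 1% between batches; response = mean
abundance per species/stage over the final 25% of the horizon (a terminal
value option exists). The ±0.10 half-width keeps the local-derivative
reading of the slope while giving the regression leverage; the windowed
response reduces year-type sampling noise relative to a terminal snapshot.

The regression is OLS of the across-replicate *mean* response on the grid
value (one point per grid value); replicate-level regression is selectable
and changes the p-values, not the slopes. Zero-variance responders get
slope 0, R² defined as 0, never retained. Retention requires `R² > 0.30`
and two-sided slope `p < 0.01`. At 21 grid points these two conditions
nearly coincide (|t| > 2.86 ⇔ R² ≳ 0.296), so the joint null retention
rate is ≈ 1%.

Slopes are reported in raw abundance per unit rate;
`SensitivityResult.standardized_slopes()` divides by the baseline mean for
cross-node comparability. The slope is a net, community-mediated effect —
not a per-capita interaction coefficient.

## Networks

Edges are retained off-diagonal (target node ≠ responder) sensitivities;
diagonal self-effects become node attributes (self-loops optional, which
switches the connectance denominator from `n(n−1)` to `n²`). Node size is
the baseline mean abundance over the same response window as the
sensitivity run. Modularity is ill-posed for signed directed graphs in the
basic formulation, so it is computed by greedy modularity maximisation on
the undirected absolute-weight projection — a stated convention, and
deterministic. Centrality defaults: betweenness on the directed graph plus
degree centrality. The triad census counts the 13 connected directed
3-node classes; all metrics are validated against exhaustive enumeration
on every directed graph with ≤ 4 nodes.

## Generator communities (what they do and do not emulate)

All vital rates in the generators are **synthetic**, chosen for clear,
documented contrasts — they are not estimates for any real system, so
passing tests demonstrate internal consistency and qualitative behaviour
(dominance, release, exclusion), not quantitative predictions for real
communities.

* `two_species_toy`: two single-stage species, constant survival
  (`s_A = 0.5 + 0.3·asymmetry`, `s_B = 0.5`), rescue-effect recruitment in
  "good" years only (frequency 0.5), `K = 100`. Single-species constant
  environment equilibrium is `n* = K/(2 − s)`, giving closed-form anchors.
* `riparian_like`: 5 guilds × 6 stages, year types flood/drought/normal at
  (0.2, 0.3, 0.5), `K = 200` space units, rescue-effect space-limited
  recruitment. Guilds trade off flood vs drought survival and differ in
  establishment year types (hydro guilds: flood; desert shrub: drought;
  etc.). Stage footprints double per stage, and the generator rescales any
  column where `P + (w_next/w) G` would exceed 0.98 — survivors can then
  never expand their total footprint, which (with the ceiling) proves
  `N ≤ K` at every census. A ±5% seeded jitter distinguishes seeds while
  preserving these caps.
* `fish_like`: n species × 4 ages, biomass-limited egg survival
  (fecundity from ages 3–4, no rescue), year types flood/drought/average
  at (0.25, 0.25, 0.5), `K = 300` biomass units, extinction threshold 1.
  Species interpolate between flood and drought affinity and gain overall
  demographic quality with their index (`quality_spread = 0.12`), so
  single-species stochastic growth rates are distinct and ordered; under
  shared regulation the community reliably collapses to a single survivor
  — the top-growth species — within ~2000 years.

Real data differ in ways the generators deliberately ignore: demographic
stochasticity, parameter uncertainty, observation error, spatial structure
and dispersal, within-year seasonality, and trophic structure beyond a
single shared resource.

## Numerical choices and problem sizes

Probability validation (`G + P ≤ 1` per column) warns by default and errors
in strict mode, because biomass/area-based models may legitimately exceed
1. Eigen-analysis uses dense `numpy.linalg.eig`; projection-vs-eigenvalue
agreement is checked at 500 renormalised steps, where every generator
matrix has subdominant ratio ≤ 0.78 and converges far below the 1e-6
tolerance. Validation simulations use: 20 replicates × 10,000 steps for the
scalar growth-rate closed form; 20 seeds × 1,000 steps for the capacity
ceiling; 200 replicates × 21 grid points × 200 steps for the toy
sensitivity; 100 protocol repetitions at 8 replicates × 50 steps for the
null-retention audit; and 100 replicates × 2,000 steps for exclusion —
sizes at which the Monte-Carlo error is comfortably below every asserted
margin.

## Known limitations

* Sensitivities are finite-difference regression slopes of a stochastic
  nonlinear system; strongly nonlinear responses within the grid window
  violate the linear-fit reading (the R² threshold filters, but cannot
  diagnose, curvature).
* Modularity and betweenness on small networks are coarse; motif counts on
  networks with < 10 nodes are mostly descriptive.
* The space-ceiling guarantee `N ≤ K` relies on non-expanding survivor
  footprints; models where survivors grow in footprint faster than they
  die can overshoot `K` (the overload is then logged, not forbidden).
* Markov regimes assume a time-homogeneous chain; non-stationary regimes
  must be supplied as explicit fixed sequences.
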