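# mcmkit — matrix community models

`mcmkit` builds, projects and analyses **matrix community models (MCMs)**:
sets of ordinary stage-structured matrix population models, one per species
or guild, coupled only through an assumption of *aggregate density
dependence*. No pairwise interaction coefficients are specified anywhere in
the model. Instead, species load a shared finite resource (space, biomass)
against a community carrying capacity `K`, and pairwise interactions —
competition, facilitation, competitive exclusion — emerge from the dynamics
and are estimated *post hoc* by cross-species sensitivity analysis and
summarised with network statistics.

It is aimed at community ecologists and demographers who have (or can
posit) environment-specific vital rates for several co-occurring species
and want to ask: *which species limit, release or exclude which others,
under which environmental regimes?*

## The model

Each species *j* follows

```
n_j(t+1) = A_j(t) n_j(t)
```

where `n_j` is the vector of stage abundances and `A_j(t)` is selected each
year from a family of matrices indexed by a discrete environmental state
("year type": flood, drought, normal, ...). Matrix entries are vital rates
tagged by role: fecundity `F`, stage transition `G`, stasis/survival `P`.
Year types are generated by an i.i.d., Markov, or fixed (historical)
regime.

Species are coupled by a **dependency assumption** on the aggregate
resource load `N(t) = Σ_j Σ_i w_ij n_ij(t)`:

* `space_limited_recruitment` — open space `max(0, K − N)` is a hard
  ceiling on the total resource claimed by new stage-1 recruits, optionally
  with a *rescue effect* (any surviving population can seed all open space
  in a favorable year, independent of adult abundance);
* `biomass_limited_fecundity` — every `F` entry is multiplied by
  `max(0, 1 − N/K)`, so reproduction approaches zero for all species as the
  community approaches `K`;
* `generic_scaling` — the same multiplicative regulation with a pluggable
  scaling function and target role.

**Cross-species sensitivity.** Because the coupled model is nonlinear and
stochastic, interaction strengths are estimated by simulation: one vital
rate is moved over a grid (default: actual value ± 0.10 in steps of 0.01),
the community is re-simulated up to 1000 times per grid value, and the
sensitivity is the OLS slope of mean abundance of every species/stage
against the perturbed rate. Edges with `R² > 0.30` and slope `p < 0.01`
are retained and assembled into a directed interaction network, summarised
by connectance, reciprocity, link density, modularity, degree/betweenness
centrality and the census of the 13 connected directed triad motifs.

## Worked example

```python
import mcmkit as mk

# two single-stage species competing for open space (K = 100);
# A survives better (s_A = 0.65 vs s_B = 0.50) and dominates
toy = mk.two_species_toy(asymmetry=0.5, seed=0)

traj = mk.project_community(toy, horizon=200, seed=3)
print({s: round(traj.totals(s)[-1], 1) for s in traj.species_ids})
# {'A': 47.2, 'B': 38.5}   <- A holds more space at the census
print(round(traj.loads.max(), 2))
# 99.52                    <- aggregate load never exceeds K = 100

# perturb A's mortality and watch both species respond
addr = mk.VitalRateAddress("A", 1, 1, parameterization="mortality")
spec = mk.PerturbationSpec(address=addr, horizon=200, replicates=50)
fit = mk.fit_sensitivity(mk.perturb_and_measure(toy, spec, seed=11))
print(fit.to_dataframe()[["responder_species", "slope", "r2", "retained"]])
#   responder_species      slope     r2  retained
# 0                 A -64.897...  0.989      True
# 1                 B  22.652...  0.989      True
```

Killing the dominant hurts itself (slope −64.9 individuals per unit
mortality, the self-effect) and releases the subordinate (+22.7): latent
competition, inferred without ever writing an interaction coefficient.

## Command line

```
mcm fixtures --name riparian_like --seed 1 --out fx     # emit a runnable config
mcm project --config fx/config.yaml --horizon 1000 --seed 1 --out run
mcm growth-rate --config fx/config.yaml --replicates 20
mcm sensitivity --config fx/config.yaml --seed 1 --out sens --resume
mcm network --sensitivity sens --r2 0.30 --p 0.01 --out net
```

Every run writes a `manifest.json` (config hash, seed, versions) sufficient
to replay it exactly. Trajectories are tidy long-format CSV
(`time, year_type, species, stage, abundance`), sensitivities a long CSV of
`(target, responder, slope, r2, p, retained)`, networks GraphML + edge-list
CSV + metrics JSON.

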