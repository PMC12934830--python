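# logddg

Diversity-dependent GeoSSE (Log-DDG) simulation and analysis.

`logddg` is for phylogeneticists and biogeographers who want to ask
whether local species richness feeds back on diversification: does a
crowded region speciate less, go locally extinct more, or receive
fewer immigrants?  The package provides a fully generative birth–death
process over discrete geographic regions in which every per-lineage
rate is modulated by the current number of sympatric species, plus the
theory and tooling around it:

* an exact (Gillespie) simulator of phylogenies with evolving ranges,
  returning complete trees, event logs, and richness trajectories;
* the **local equilibrium diversity** `n*` implied by a parameter set —
  the emergent regional carrying capacity at which incoming rate
  (speciation + immigration) balances outgoing rate (extinction) —
  solved numerically or analytically;
* tree-shape statistics (Aldous β, Pybus–Harvey γ, mean range size,
  treeness) and mesh-grid simulation experiments over effect strengths;
* a training-set generator for likelihood-free (simulation-based)
  inference, writing Newick trees, one-hot tip-range tables, and
  parameter labels.

## The model

Each lineage occupies a range (nonempty subset of `R` regions) with
regional richness `n_i(t)` = number of extant species present in
region *i*.  Rates multiply a base rate by `(ln x + 1)^p`:

| process | rate |
|---|---|
| within-region speciation (budding) | `w_i = rho_w (ln n_i + 1)^{w_D}` |
| extinction / range loss in *i* | `e_i = rho_e (ln n_i + 1)^{e_D}` |
| dispersal *i → j* | `d_ij = rho_d (ln n_i + 1)^{d_D_src} (ln(n_j+1) + 1)^{d_D_dest}` |
| allopatric split `m -> {k, l}` | `rho_b * f_b(k, l)` with edge weights `(ln(n_i n_j) + 1)^{b_D}` |

With all exponents zero this is exactly constant-rate GeoSSE.  Under
the symmetric balance equation `w_i + Σ_j d_ji = e_i` the model admits
a local equilibrium diversity, e.g. in closed form (for `d_D_src = 0`,
`w_D = d_D_dest = y`):

```
n* = exp( [ (rho_w + rho_d (R − 1)) / rho_e ]^{1/(e_D − y)} − 1 )
```

See `docs/methods.md` for the full model description, solver details,
and numerical choices.

## Worked example

```python
from logddg import (DDParams, EquilibriumProblem, StopCondition,
                    closed_form_equilibrium, solve_equilibrium_numeric,
                    simulate, prune_to_extant, gamma_statistic)

params = DDParams(rho_w=0.610047, rho_e=0.01, rho_d=0.01, rho_b=1.0,
                  w_D=-1.0, d_D_dest=-1.0, e_D=2.0, n_regions=3)

print(closed_form_equilibrium(params))
# 19.671210197287536        <- analytic equilibrium, species per region
print(solve_equilibrium_numeric(EquilibriumProblem(params)))
# 19.661011085345525        <- exact balance equation (no ln(n+1) ~ ln n)

sim = simulate(params, StopCondition(max_time=300.0), root_range={0}, seed=42)
print(sim.richness())
# [18 18 17]                <- terminal per-region richness of one replicate
tree = prune_to_extant(sim)
print(gamma_statistic(tree))
# 5.336220220069261         <- node depths pile up near the present
```

The analytic and simulated richness agree: a 3-region clade seeded by
one species in one region grows until each region hosts about 19
coexisting species, then plateaus.  The large positive γ reflects the
equilibrium regime — at carrying capacity, turnover keeps divergence
times clustered near the present.

The same is available from the shell:

```bash
logddg equilibrium --rho-w 0.610047 --rho-e 0.01 --rho-d 0.01 --rho-b 1 \
    --w-d -1 --d-d-dest -1 --e-d 2 --n-regions 3 --solver closed-form
# n_star    19.671210
logddg trainset --submodel 7 --n 100 --out train/ --seed 1
logddg gridstudy --points-per-axis 3 --reps 20 --seed 1 --out grid.csv
```

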