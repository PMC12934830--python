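# Methods

## The model

`logddg` implements a diversity-dependent GeoSSE birth–death process.
Each lineage carries a geographic range — a nonempty subset of `R`
discrete regions — and evolves through four event types:

* **within-region speciation** (budding): a lineage occupying region
  *i* produces a daughter endemic to *i* at per-region rate
  `w_i = rho_w (ln n_i + 1)^{w_D}`;
* **extinction / range contraction**: region *i* is removed from the
  range at rate `e_i = rho_e (ln n_i + 1)^{e_D}`; when the range was
  `{i}` the lineage dies;
* **dispersal**: region *j* is added to the range at rate
  `d_ij = rho_d (ln n_i + 1)^{d_D_src} (ln(n_j + 1) + 1)^{d_D_dest}`
  per occupied source *i*;
* **between-region (allopatric) speciation**: a widespread range *m*
  splits into an unordered bipartition `{k, l}` at rate
  `rho_b * f_b(k, l)`, where `f_b` is the inverse of the summed inverse
  mean edge weights over the cut set `E(k, l)` and each edge weight is
  `(ln(n_i n_j) + 1)^{b_D}`.

Here `n_i(t)` is the number of extant species whose range contains
region *i*.  Every factor equals 1 when the relevant count is at its
"alone" value (`n_i = 1`; `n_j = 0` for a dispersal destination;
`n_i = n_j = 1` for a split edge) or the exponent is 0, so the model
reduces exactly to constant-rate GeoSSE when all exponents vanish.
Logarithms are natural throughout: diversity acts on the order of
magnitude of richness, not on raw counts.

Interpretation of the rate-factor arguments (count for the
source-style factors, count + 1 for the destination factor, product of
counts for split edges) is the unique reading consistent with all of
the neutrality conditions above, and is fixed as such here.

### Parameters

| parameter | meaning | units | typical range |
|---|---|---|---|
| `rho_w, rho_e, rho_d, rho_b` | base event rates | events / lineage / time | `[1e-4, 1]` in training priors |
| `w_D` | richness effect on within-region speciation | exponent | `[-2, 0]` (competition) |
| `e_D` | richness effect on extinction | exponent | `[0, 2]` (competition) |
| `d_D_src`, `d_D_dest` | effects on outbound / inbound dispersal | exponent | `d_D_dest in [-2, 0]`; `d_D_src = 0` in all study designs |
| `b_D` | effect on range-split edge weights | exponent | 0 in all study designs |
| `n_regions` | number of regions | count | 3 (theory / grids), 5 (training sets) |

Region adjacency is not modelled: the region graph is complete, so the
cut set of a bipartition `(k, l)` is the full bipartite product
`k × l`.  The proportionality constant of the split score is 1, which
makes a single-edge cut with unit weight give `f_b = 1` and hence the
base rate exactly.  Between-region speciation enumerates all
`2^(|m|-1) - 1` unordered bipartitions of the parent range, each with
its own rate.

## Simulation

Rates are constant between events, so the process is simulated exactly
(Gillespie): an exponential waiting time at the summed rate, then a
single uniform draw over the cumulative per-lineage rate table in
fixed lineage-id order.  Lineages sharing a range have identical rate
tables, so one table per distinct range is computed per step.  The
full tree (extinct lineages included) and a complete event log are
returned; replaying the log against the initial state reproduces the
final lineage table, and this identity is asserted in the test suite
on every simulated fixture.

Stopping: a hard `max_time`, and optionally a taxon cap — when the
extant count reaches the cap the simulation stops at that event's time
and the event is kept.  Extant-only trees are obtained by pruning
extinct lineages and suppressing unifurcations; the pruned tree is
rooted at the most recent common ancestor of the survivors (the origin
stem is dropped), which is the standard reconstructed-tree convention
and makes fixed-time trees ultrametric.

## Equilibrium diversity

The local equilibrium diversity `n*` solves the per-region balance
equation `w_i + sum_j d_ji = e_i` under the symmetric assumption that
every region targets the same richness (without it the balance is
under-determined).  Richness is relaxed to a continuous variable
`n >= 1`; simulated richness is integer-valued, so comparisons with
theory use means over replicates.

Three solvers are provided:

* **numeric** — Brent root-finding on the residual over a default
  bracket `[1 + 1e-6, 1e4]`, residual tolerance `1e-8`, after an
  explicit Bolzano sign-change check (a missing sign change raises a
  no-equilibrium error rather than returning a spurious root);
* **closed form** — valid when `d_D_src = 0` and `w_D = d_D_dest = y`:
  `n* = exp(((rho_w + rho_d (R-1)) / rho_e)^(1/(e_D - y)) - 1)`;
* **fixed point** — valid when `w_D = d_D_src = d_D_dest = x`: damped
  iteration of
  `n <- exp(((rho_w + rho_d (R-1)(ln n + 1)^x) / rho_e)^(1/(e_D - x)) - 1)`,
  halving the damping on non-convergence and falling back to a
  bracketing root-finder for oscillatory cases.

The numeric residual keeps the exact `ln(n + 1) + 1` destination
factor while both analytic forms use the `n >> 1` approximation
`ln(n + 1) ~ ln n`; this approximation gap is the documented source of
the (under 2% for `n* > 10`) disagreement between solvers, and the
cross-solver agreement is property-tested on 200 random parameter sets.

## Tree statistics

* **γ (Pybus–Harvey)** — computed from internode intervals of the
  ultrametric extant-only tree, measured from the crown split;
  ultrametricity is checked to `1e-6` of tree height.  Cross-checked
  against dendropy's implementation to `1e-6`.
* **Aldous β** — maximum-likelihood exponent of the beta-splitting
  model from the (left, right) clade sizes at every bifurcation,
  maximized by bounded search on `[-2, 10]` and verified on a 400-point
  grid; estimates within `1e-3` of a bound are reported as the bound.
  Cross-checked against an independent brute-force likelihood grid.
* **mean range size** — mean number of occupied regions per extant tip
  from the one-hot tip-state table.
* **treeness** — internal branch length over total branch length.  The
  statistic is sometimes described relative to tree height, but only
  the length-proportion definition is bounded in `[0, 1]` and matches
  the empirical ranges the statistic is quoted with, so that definition
  is used here.

The mesh-grid experiment varies `(w_D, e_D, d_D_dest)` on evenly
spaced points over `[-2, 0] × [0, 2] × [-2, 0]` (or `±0.1` for the
weak-effect design) with base rates `rho_w = rho_d = 0.05`,
`rho_e = rho_b = 0.02`, excluding the all-zero cell.  Published totals
(49,950 and 6,200 trees) correspond to 10 and 5 points per axis with
50 trees per cell; points-per-axis is configurable.  Conditioning "on
tree height 100" is implemented by rejection: simulate to time 100 and
accept if at least 3 extant tips survive.  Cells whose retry budget
runs out are flagged in the output, not fatal.

## Training datasets

Five-region simulations with `d_D_src = b_D = 0`.  Eight submodels
toggle diversity dependence on extinction (`e_D ~ U(1e-4, 2)`),
within-region speciation (`w_D ~ U(-2, -1e-4)`), and inbound dispersal
(`d_D_dest ~ U(-2, -1e-4)`); inactive exponents are exactly 0.  Base
rates are drawn from a 50/50 mixture of uniform and log-uniform
distributions on `[1e-4, 1]`, assigned deterministically by replicate
parity so any dataset size preserves the split.  Each replicate draws
its own taxon cap (`U(100, 300)`, rounded to an integer — counts are
integers) and stop time (`U(70, 100)`), starts from a single ancestral
species in a uniformly chosen region (recorded in the labels), and
stops at the first of time or taxon cap.  Rejection sampling redraws
on total extinction or fewer than 10 extant tips.  Each accepted
replicate is written as `<id>.tre` (Newick), `<id>.dat.csv` (one-hot
tip ranges), `<id>.labels.csv`, plus a combined `manifest.csv`; every
replicate uses an independent child seed spawned from the dataset
seed, so results are identical whether replicates are generated
serially or in parallel.

## What the simulations do and do not show

The generator produces clean, completely sampled, dated trees with
exact tip ranges.  It does not emulate incomplete taxon sampling,
fossil/serial sampling, dating error, range-assignment error, or
region-specific features (area, adjacency, covariates) — so passing
tests demonstrate internal correctness of the process and its theory,
not robustness to the measurement error real phylogenies carry.

## Numerical choices and problem sizes

* Stochastic equilibrium validation: 100 replicates of the constrained
  3-region model run to time 300.  The richness trajectories flatten
  well before time 200 (the half-time mean is within half a species of
  the terminal mean), so time 300 comfortably samples the plateau.
* Trend recovery uses the reduced grid (3 points per axis, 20 trees
  per cell, 520 accepted trees) and checks Spearman rank-correlation
  signs across cell means.
* Yule reduction: 2,000 replicates, chi-square test against the
  geometric lineage-count law with right-tail bins pooled below an
  expected count of 5.
* Constant-rate GeoSSE reduction: 800 replicates against an
  independent direct simulation, compared within four standard errors.
* Gillespie event selection resolves float roundoff at cumulative-table
  boundaries by falling back to the last entry of the implicated
  lineage; ties cannot otherwise occur under continuous waiting times.

## Known limitations

* Unequal per-region equilibria are out of scope (the symmetric
  balance equation is under-determined without extra assumptions).
* The linear (non-logarithmic) diversity-dependence variant is not
  implemented.
* `b_D != 0` is fully supported in the rate machinery but none of the
  quantitative study designs exercise it, so it is validated only by
  unit and property tests.
* Downstream neural-network encoding, training, and model selection
  are outside this package; it produces the training files only.
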