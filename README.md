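# phylospread

Can Bayesian phylogeography find the homeland of a language family from a
time-calibrated tree and the present-day locations of its languages?  The
answer depends on *how* the family spread.  This package provides the full
desk-scale machinery to study that question:

* **MigSim** — migration as a directional random walk: point-languages step
  every year by N(μ/T, σ²/T) per coordinate while splitting (rate λ) and
  dying (rate ν) in a birth–death process.  The aggregate parameters are the
  total bias μ (km over the whole period T) and the total diffusion distance
  σ.  Defaults follow T = 5000 yr, σ = 2000 km, ν = ln N/4T = 0.00023,
  λ = 5ν = 0.00115, giving an expected N = 100 extant languages.
* **ExpSim** — expansion as constrained region growing: area-languages on a
  100 × 100 km cell grid claim neighbouring cells with per-language growth
  probability p_grow ~ U[0, 1] and split into two connected daughters upon
  reaching a size drawn from U{70..100} cells.  Directional trend is imposed
  geometrically by confining growth to a circular sector of angle α; α = 2π
  is a free concentric expansion, α = 0.2π a narrow corridor.
* **Reconstruction** — Brownian diffusion along the fixed true tree: the
  displacement down a branch of duration t is bivariate normal with mean
  d·t and per-coordinate variance σ²·r·t.  Four flavours: homogeneous RW
  (r ≡ 1, d ≡ 0; root posterior available in closed form by Gaussian
  pruning), relaxed RRW (per-branch lognormal rate multipliers r), CDRW
  (constant drift vector d) and RDRW (per-branch drifts around a global
  mean).  Inference is Metropolis-within-Gibbs with exact Gaussian
  full-conditionals for node locations, conjugate updates for σ² and
  drift, and parallel log-scale Metropolis for the rates.  Known historical
  locations ("fossils") enter as observed degree-2 nodes on their branch.
* **Evaluation** — observed trend μ̂ = ‖Σxₙ/N − X‖ (tip centroid vs true
  root X), RMSE = √(Σ‖X̂ₘ − X‖²/M) over posterior draws, bias =
  ‖ΣX̂ₘ/M − X‖, and HPD-region coverage at 80%/95% via a kernel density
  criterion.
* **Tree statistics** — corrected Fusco–Cronk tree imbalance, convex-hull
  clade overlap, and diversity–space dependence (sister contrasts of clade
  size vs phylogenetically corrected expansion rate): three numbers that
  tell migration-shaped data apart from expansion-shaped data.

The headline phenomenon: under directed migration the reconstruction is off
by roughly the directional trend itself (the model can only place the root
inside the convex hull of the tips), while under constrained expansion the
early-splitting, stationary clades near the homeland anchor the
reconstruction and the error stagnates at a small fraction of the trend.

## Worked example

```python
from phylospread import (MigSimParams, simulate_migration, ModelSpec,
                         mcmc_sample, evaluate_run, compute_stats)

res = simulate_migration(MigSimParams(mu=(3000.0, 0.0)), seed=11,
                         keep_trajectories=False)
print("extant languages:", res.n_extant)
print("observed trend:  %.0f km" % res.observed_trend)

tree = res.tree.prune_to_extant()
spec = ModelSpec(kind="rrw", iterations=20000, burn_in=0.25, thinning=10)
samples = mcmc_sample(tree, res.tip_locations, spec, seed=11)
report = evaluate_run(samples.root, res.root_location, res.tip_locations)
print("posterior root mean: (%.0f, %.0f) km" % tuple(samples.root.mean(0)))
print("bias: %.0f km   RMSE: %.0f km" % (report.bias, report.rmse))
print("root covered by 95% HPD region:", report.covered_95)

stats = compute_stats(tree, res.tip_locations)
print("imbalance %.2f  overlap %.2f  dependence %.2f" % (
    stats.tree_imbalance, stats.clade_overlap,
    stats.diversity_space_dependence))
```

prints

```
extant languages: 61
observed trend:  4427 km
posterior root mean: (3909, 1598) km
bias: 4223 km   RMSE: 4613 km
root covered by 95% HPD region: False
imbalance 0.54  overlap 0.40  dependence -0.02
```

The simulated family drifted 4427 km east of its homeland at the origin;
the relaxed random walk places the root near the tip centroid, 4223 km off,
and its 95% credible region misses the truth — the migration failure mode
in one run.  The tree statistics show the migration signature: birth–death
balance (≈ 0.5), substantial spatial interleaving of clades, no
diversity–space dependence.  Re-running with `simulate_expansion` at
α = 0.2π instead produces a strongly imbalanced tree whose reconstruction
lands within a few hundred kilometres of the founder cell.

A command-line interface mirrors the library:

```bash
phylospread simulate-mig --mu 3000 --seed 11 --out-prefix run1
phylospread reconstruct --tree run1.extant.nwk --locations run1.locations.tsv \
    --model rrw --iterations 20000 --seed 1 --out samples.csv
phylospread evaluate --samples samples.csv --truth 0,0 \
    --tips run1.locations.tsv --out report.csv
phylospread sweep --scenario exp --models rrw --replicates 10 --seed 7 \
    --out sweep.csv
```

## Layout

```
src/phylospread/
  core.py         shared tree/location/fossil types, Newick + TSV + config IO
  migsim.py       directional random-walk migration simulator
  expsim.py       constrained grid-growth expansion simulator
  phylogeo.py     Brownian-diffusion reconstruction (analytic RW + MCMC)
  evalmetrics.py  trend, RMSE, bias, HPD coverage
  treestats.py    imbalance, clade overlap, diversity-space dependence
  experiments.py  sweep orchestration and aggregation
  cli.py          command-line interface
docs/methods.md   model and design notes
```
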