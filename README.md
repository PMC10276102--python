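# barseqfit

Per-lineage fitness inference for barcoded pooled competition assays.

Large libraries of barcoded strains are competed in one pot through serial
batch culture, and each lineage's relative abundance is tracked by
amplicon sequencing of the barcode locus. `barseqfit` turns those
read-count time series into per-lineage **Malthusian fitness** estimates
`ŝ` (per-generation growth rate relative to the pool) and **initial
bottleneck cell numbers** `n̂₀`, and ships a full forward simulator of the
experiment so inference accuracy can be validated by parameter recovery.

## The model

At sequencing times `t₀ < t₁ < … < t_K` (generations), lineage reads `r_k`
(of `R_k` total) reflect latent bottleneck cells `n_k` (of `N_k` total).
A lineage's expected frequency fold-change over an interval is

    E_k = exp[(t_k − t_{k−1}) s − ∫ s̄(t) dt],

with `s̄(t)` the population mean fitness (piecewise linear between
sequenced points). The joint likelihood of `(s, n₀)` chains two
square-root-scale branching-process kernels — growth/transfer noise `c_k`
and sequencing-pipeline noise `β_k` — over the latent cell path, which is
eliminated by maximizing the integrand via a tridiagonal linear solve.
Per-lineage optimization is by differential evolution; fitness and mean
fitness are estimated by alternating iteration. The read-noise default is
derived from the experimental design as
`β = (r̄/n̄ + 2r̄/n_DNA + 1)/2`. The older single-noise-scale
read-to-read likelihood is included as `method="legacy"` for comparison.
See `docs/methods.md` for the complete account.

## Worked example

```python
import barseqfit as bf

# simulate a pooled competition: 200 lineages, 20 generations in
# 4-generation cycles, 100 reads/lineage, all five noise layers
config = bf.SimulationConfig(n_lineages=200, reads_per_lineage=100.0, seed=42)
truth = bf.simulate_experiment(config)

# estimate fitness and initial cell number for every lineage
est = bf.FitnessEstimator(
    method="joint", time_points=truth.time_points,
    cells_per_lineage=100.0, random_state=0,
)
est.fit(truth.read_matrix)

report = bf.evaluate(truth, est.result_)
print(f"iterations: {est.n_iter_}, converged: {est.converged_}")
print(f"pearson(s*, s_hat) = {report.pearson_s:.3f}")
print(f"mean |s* - s_hat|  = {report.mae_s:.4f}")
print(f"pearson(n0*, n0_hat) = {report.pearson_n0:.3f}")
```

prints

```
iterations: 10, converged: True
pearson(s*, s_hat) = 0.977
mean |s* - s_hat|  = 0.0224
pearson(n0*, n0_hat) = 0.907
```

The fitted estimator exposes `fitness_` (ŝ per lineage), `n0_`,
`reads_hat_` (reconstructed trajectories `r̂_k = n_k R_k / N_k`),
`mean_fitness_` (the `s̄(t_k)` curve), and `objective_history_` (the
summed negative log-likelihood per iteration, non-increasing across
accepted iterations). A Pearson correlation of 0.98 against the simulated
truth and a mean absolute fitness error of ~0.02 per generation mean the
method recovers selection coefficients down to a few percent per
generation at this read depth; initial cell numbers are recovered to
within the sampling noise of a ~100-cell bottleneck.

The same pipeline is available from the shell:

```sh
barseqfit simulate -L 1000 -r 100 --seed 1 --out sim/
barseqfit fit --counts sim/reads.csv --cells-per-lineage 100 --out fit/
barseqfit evaluate --truth sim/truth.csv --fit fit/ --out metrics.json
```

Count tables are plain CSV with lineages as rows and time points in the
header (`lineage,t0,t4,…`); the joint method additionally needs the
bottleneck census, either `--total-cells N₀,…,N_K` or
`--cells-per-lineage n̄` (expanded as `N_k = n̄·L`).

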