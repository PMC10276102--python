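# Methods

## The estimation problem

A pooled competition assay follows `L` barcoded lineages through serial
batch culture: `g` generations of growth, a `2^-g` dilution ("transfer"),
repeated until generation `T`. At sequencing time points
`t_0 < t_1 < ... < t_K` (generations) lineage `i` holds `n_k` cells at the
bottleneck out of `N_k` total and receives `r_k` reads out of `R_k` total.
The quantity of interest is each lineage's Malthusian fitness `s` — its
per-generation exponential growth rate relative to the pool — and,
secondarily, its initial bottleneck cell number `n_0`.

The expected change of a lineage's frequency over the interval
`(t_{k-1}, t_k]` is the growth factor

    E_k = exp[ (t_k - t_{k-1}) s  -  ∫ s̄(t) dt ],

where `s̄(t)` is the population mean fitness, inferred only at sequenced
points and interpolated linearly between them; the integral is therefore
evaluated exactly by the trapezoid rule. The mean-fitness term is what the
naive fold-enrichment estimate omits: a modestly beneficial lineage rises
early, then declines once `s̄(t)` overtakes its own fitness, so two-point
estimators mistake it for deleterious.

## Likelihoods

**Joint (cell-path) likelihood.** The read count `r_k` depends on the
latent cell count `n_k`, not on `r_{k-1}`. Two square-root-scale Gaussian
transition kernels — the branching-process (Gaussian-on-√n) approximation —
link consecutive states:

* growth/transfer: exponent `-(√n_k - √(n_{k-1} E_k))² / c_k`, where `2c_k`
  is the per-individual offspring-number variance per growth cycle
  (`c_k = 1` by default);
* sequencing pipeline: exponent `-(√r_k - √(n_k R_k/N_k))² / β_k`, where
  `2β_k` is the per-read variance accumulated over DNA extraction, PCR and
  sequencing.

Only the exponents are kept (normalizing prefactors dropped), so reported
objective values are negative log-likelihoods up to an additive constant —
this is recorded in the output metadata. The joint likelihood of
`(s, n_0)` multiplies these kernels over `k = 1..K`, plus the `k = 0` read
term `-(√r_0 - √(n_0 R_0/N_0))²/β_0` that ties `n_0` to the first
observation, and integrates over the latent path `n_1..n_K`. The integral
is replaced by the maximum of its integrand: the exponent is quadratic in
`ν_k = √n_k`, so the maximizer solves a symmetric positive-definite
tridiagonal linear system, computed by the Thomas algorithm in `O(K)`.
Negative components of the solution (possible for near-extinct lineages)
are clamped to zero — `ν = √n` cannot be negative — and the lineage is
flagged.

The per-read noise default is derived from the experimental design:

    β = (r̄/n̄ + 2 r̄/n_DNA + 1) / 2,

summing the reverse-dilution (`r̄/n̄`), extraction (`r̄/n_DNA`), PCR
(`r̄/n_DNA`) and sequencing (1) contributions to the per-read variance
`2β`. At the reference design (`r̄ = 50`, `n̄ = 100`, `n_DNA = 500`) this
gives `β = 0.85`; at `r̄ = 20` it gives `0.64` and at `r̄ = 100` it gives
`1.2`. `β` is evaluated per time point from the observed mean depth
`r̄_k = R_k/L` unless overridden.

**Legacy (read-to-read) likelihood.** The older single-layer model chains
reads directly, `p(r_k | r_{k-1}, s)`, with one noise scale `κ` and the
full density including its prefactor. Because `r_k^{3/2}` and the
predicted mean sit inside the density, any zero read along a trajectory
makes it undefined; such lineages receive a `nan` sentinel and should be
scored by the joint likelihood instead. No published value of `κ` exists
for this kernel's use here; the default `κ = 2.5` matches the scale of the
combined noise layers at the reference design and is user-overridable.

## Iterative procedure

Fitness and mean fitness are mutually dependent, so estimation alternates:

1. initialize `s̄ ≡ 0` (joint mode) or from log-linear regression of the
   first two time points (legacy mode);
2. optimize each lineage independently under the current curve;
3. update `s̄(t_k) = Σ_i ŝ_i f_{i,k}` with observed read frequencies;
4. stop when the summed objective fails to decrease, or improves by less
   than a relative `1e-4` (guarding against float-noise infinite loops), or
   at `max_iter`.

**Gauge fixing.** The likelihood depends on `s` only through `s - s̄`, so
adding the same constant to every fitness and to the whole curve changes
nothing — the data determine fitness only up to an additive constant. The
package anchors the gauge by the convention that defines fitness in the
first place: relative to the initial population, whose frequency-weighted
mean fitness is zero, `Σ_i ŝ_i f_{i,0} = 0`. The re-gauge is applied after
every iteration and is exact (objective values are untouched). Simulated
truths are compared in the same gauge.

**Per-lineage optimization.** The joint objective is optimized over
`(s, log n_0)` — the log scale makes the initial-cell box symmetric
multiplicatively — by differential evolution (best/1/bin, population 15 per
dimension), a gradient-free global search suited to the clamped,
non-differentiable-in-corners landscape, followed by L-BFGS-B polishing of
the best point. The search budget (`de_maxiter = 120`, `de_tol = 1e-3`)
is chosen so that differential evolution locates the basin and polishing
supplies the precision; the landscape is unimodal in practice, and this
combination reproduces zero-noise truths to `1e-3` in `s` at a fraction of
the cost of running the population search to convergence. All
hyperparameters are exposed. Bounds: `s ∈ [-1, 1]`; `n_0` within a factor
50 of the plug-in `ñ_0 = r_0 N_0 / R_0` (for `r_0 = 0`, the first nonzero
time point is mapped back through neutral growth factors). Later outer
iterations refine the previous optimum with L-BFGS-B instead of repeating
the global search (`global_search_iters = 1`): the optimum moves
continuously with the mean-fitness curve, and the refinement keeps the
iteration cost linear in `L` with small constants. Legacy mode is a
bounded 1-D Brent minimization over `s`.

**Determinism.** Each lineage's optimizer seed derives from the master
seed and a CRC of the lineage identifier, so results are independent of
row order and of the parallel degree (`n_jobs` chunks merely partition
work). Exact bit-reproducibility holds for a fixed lineage set; permuting
rows changes only summation order in the mean-fitness update (float-level
differences).

## Simulator

The generator emulates the full experiment with five Poisson noise layers:

1. **growth** — per generation, lineage counts are resampled as
   `Pois(2 n_i e^{s_i} · Σ_j n_j / Σ_j n_j e^{s_j})`: doubling weighted by
   relative fitness, so the total population doubles in expectation and a
   neutral cell's offspring count is `Pois(2)` (variance 2, matching
   `2c = 2`). A literal, unnormalized transcription of the growth update
   (`Pois(2 n_i e^{s_i} / Σ_j n_j e^{s_j})`) is dimensionally degenerate —
   it collapses the population within one generation — and is kept only
   behind `growth_normalization="as_printed"` for comparison;
2. **transfer** — `Pois(n_i/2^g)` per lineage at the end of each cycle;
3. **DNA extraction** — expected `500·L` template copies allocated
   proportionally to saturated lineage sizes;
4. **PCR** — 25 cycles of stochastic doubling `t ← t + Pois(t)`;
5. **sequencing** — expected `r·L` reads allocated proportionally to
   post-PCR copies.

Sequencing happens at `t = 0` (from the initial bottleneck, before any
growth) and at every transfer, from the saturated pre-dilution population —
the same population the bottleneck is drawn from, which is what makes the
reverse-dilution term `r̄/n̄` appear in `β`. Extraction and sequencing use
independent per-lineage Poisson draws with proportional means
(Poissonization of multinomial sampling), so column totals are random with
the stated expectations.

Defaults are the standard study conditions: `L = 10^4` lineages, `T = 20`
generations in `g = 4`-generation cycles, `r ∈ {20, 50, 100}` reads per
lineage, initial cells `~ Gamma(shape 20, rate 0.2)` (mean 100, variance
500) rounded to integers, `n_DNA = 500`, 25 PCR cycles. Fitness is drawn
from a normal DFE (`σ = 0.15`) or skew-normal (`scale 0.225`, shape `±3`),
mean-centered, and truncated to `[-1, 1]`. A uniform-initial-size mode
(`uniform_initial_cells = 100`) reproduces the older simulation protocol.

What the generator does *not* emulate: barcode chimeras and PCR/sequencing
base errors, cross-contamination, frequency-dependent or time-varying
fitness, and chemostat (continuous) growth. Passing recovery tests on this
generator therefore demonstrates correctness of the inference under the
modeled noise sources, not robustness to artifacts outside the model.

`deterministic_reads` produces the zero-noise skeleton of the same model —
real-valued trajectories satisfying `n_k = n_{k-1} E_k` under the
self-consistent (fixed-point) mean-fitness curve — for which the joint
likelihood is exactly zero at the truth; it is the reference input for
optimizer-correctness tests.

## Numerical choices and edge cases

* Tridiagonal solve: Thomas algorithm with explicit zero-pivot detection
  (`DegenerateSystemError`); the system is symmetric positive definite for
  valid inputs, so this fires only on degenerate user input.
* Zero reads are legal in the joint likelihood (`γ_k = 0`); all-zero rows
  are fit with a floor plug-in `ñ_0 = 0.1`.
* Legacy zero-read lineages: `nan` sentinel, excluded from the summed
  objective; they contribute zero (not their frequency-weighted fitness)
  to the mean-fitness update.
* Ties in `fraction_improved` count as "not improved" (strict inequality).
* Convergence histories keep every probed iteration; the accepted prefix
  is non-increasing by construction.

## Problem sizes used in the test suite

Unit and property tests run at `K ≤ 50`, `L ≤ 100`. Recovery tests use
`L = 1000` lineages (three replicate seeds, read depths 20/50/100) — a
deliberate reduction from the `L = 10^4` standard configuration that keeps
the full suite fast while leaving the per-lineage statistics unchanged
(each lineage's likelihood involves only its own trajectory; `L` enters
only through the precision of the mean-fitness curve, which is already
sub-1% at `L = 1000`). Simulator calibration checks run at the full
`L = 10^4`.
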