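"""Forward simulation of pooled serial-batch competition experiments.

Starting from ``L`` barcoded lineages with Gamma-distributed initial cell
numbers and fitnesses drawn from a configurable distribution, the simulator
runs ``T`` generations of growth in batches of ``g`` generations, with five
stochastic layers, each Poisson:

1. growth — every generation each lineage's cell count is resampled with
   mean ``2 n_i e^{s_i} * (sum_j n_j) / (sum_j n_j e^{s_j})``: cells double
   on average, weighted by relative fitness, so the total population doubles
   in expectation each generation;
2. transfer — at the end of each batch the bottleneck sample is
   ``Pois(n_i / 2^g)`` per lineage;
3. genomic DNA extraction — an expected ``500 L`` template copies allocated
   proportionally to saturated lineage sizes;
4. PCR — 25 cycles of stochastic doubling, ``t <- t + Pois(t)`` per cycle;
5. sequencing — an expected ``r L`` reads allocated proportionally to
   post-PCR copy numbers.

Sequencing happens at ``t = 0`` (from the initial bottleneck) and at every
transfer, yielding ``T/g + 1`` time points.  The returned
:class:`SimulationTruth` carries the observed read matrix alongside the true
per-lineage fitnesses, initial cells and bottleneck cell paths, so inference
accuracy can be scored by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "sample_fitness",
    "sample_initial_cells",
    "grow_one_generation",
    "bottleneck_transfer",
    "library_prep_and_sequence",
    "simulate_experiment",
    "deterministic_reads",
]

_DFE_NAMES = ("normal", "skew_left", "skew_right")


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one simulated pooled-growth experiment.

    Defaults are the standard study conditions: 10^4 lineages followed for 20
    generations in 4-generation cycles, Gamma(20, 0.2) initial sizes (mean
    100 cells/lineage), 500 DNA copies/lineage, 25 PCR cycles, and a normal
    distribution of fitness effects with sigma = 0.15 (or a skew-normal with
    scale 0.225 and shape +/-3).
    """

    n_lineages: int = 10000
    total_generations: int = 20
    generations_per_cycle: int = 4
    reads_per_lineage: float = 50.0
    dfe: str = "normal"
    dfe_loc: float = 0.0
    dfe_scale: float | None = None
    dfe_shape: float | None = None
    gamma_alpha: float = 20.0
    gamma_rate: float = 0.2
    uniform_initial_cells: float | None = None
    n_dna_per_lineage: float = 500.0
    pcr_cycles: int = 25
    growth_normalization: str = "relative"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        if self.total_generations % self.generations_per_cycle != 0:
            raise ValueError("total_generations must be divisible by generations_per_cycle")
        if self.generations_per_cycle < 1:
            raise ValueError("generations_per_cycle must be >= 1")
        if self.dfe not in _DFE_NAMES:
            raise ValueError(f"unknown DFE {self.dfe!r}; choose from {_DFE_NAMES}")
        for name in ("reads_per_lineage", "gamma_alpha", "gamma_rate",
                     "n_dna_per_lineage"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.growth_normalization not in ("relative", "as_printed"):
            raise ValueError("growth_normalization must be 'relative' or 'as_printed'")

    @property
    def n_cycles(self) -> int:
        return self.total_generations // self.generations_per_cycle

    @property
    def time_points(self) -> np.ndarray:
        """Sequenced times ``0, g, 2g, ..., T`` in generations."""
        return np.arange(self.n_cycles + 1) * float(self.generations_per_cycle)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth and observations from one simulated experiment."""

    s_true: np.ndarray
    n0_true: np.ndarray
    cell_paths: np.ndarray
    read_matrix: np.ndarray
    time_points: np.ndarray
    config: SimulationConfig

    @property
    def totals(self) -> np.ndarray:
        """Per-time-point total read depth ``R_k``."""
        return self.read_matrix.sum(axis=0).astype(float)

    @property
    def bottleneck_totals(self) -> np.ndarray:
        """Per-time-point total bottleneck cells ``N_k``."""
        return self.cell_paths.sum(axis=0).astype(float)


def sample_fitness(
    dfe: str,
    n_lineages: int,
    rng: np.random.Generator,
    loc: float = 0.0,
    scale: float | None = None,
    shape: float | None = None,
) -> np.ndarray:
    """Draw per-lineage fitnesses from a distribution of fitness effects.

    ``"normal"`` uses sigma 0.15 by default; ``"skew_left"``/``"skew_right"``
    use a skew-normal with scale 0.225 and shape -3/+3.  Draws are centered
    to mean zero (fitness is relative to the pool) and truncated to
    ``[-1, 1]``.
    """
    if dfe == "normal":
        scale = 0.15 if scale is None else scale
        s = rng.normal(loc, scale, size=n_lineages)
    elif dfe in ("skew_left", "skew_right"):
        scale = 0.225 if scale is None else scale
        default_shape = -3.0 if dfe == "skew_left" else 3.0
        a = default_shape if shape is None else shape
        s = stats.skewnorm.rvs(a, loc=loc, scale=scale, size=n_lineages,
                               random_state=rng)
    else:
        raise ValueError(f"unknown DFE {dfe!r}; choose from {_DFE_NAMES}")
    s = s - s.mean()
    return np.clip(s, -1.0, 1.0)


def sample_initial_cells(
    gamma_alpha: float, gamma_rate: float, n_lineages: int, rng: np.random.Generator
) -> np.ndarray:
    """Gamma(shape, rate) initial bottleneck cells, rounded to integers."""
    if gamma_alpha <= 0 or gamma_rate <= 0:
        raise ValueError("gamma parameters must be positive")
    draws = rng.gamma(shape=gamma_alpha, scale=1.0 / gamma_rate, size=n_lineages)
    return np.maximum(np.rint(draws), 0.0).astype(np.int64)


def grow_one_generation(
    n: np.ndarray,
    s_true: np.ndarray,
    rng: np.random.Generator,
    normalization: str = "relative",
) -> np.ndarray:
    """One generation of noisy growth for all lineages.

    Each lineage is resampled as ``Pois(2 n_i e^{s_i} * W)``.  With the
    default ``"relative"`` normalization ``W = sum_j n_j / sum_j n_j e^{s_j}``,
    so a cell's expected offspring number is 2 times its relative fitness
    weight and the total population doubles in expectation; the per-cell
    offspring variance for a neutral lineage is 2.  ``"as_printed"`` uses
    ``W = 1 / sum_j n_j e^{s_j}`` instead (a literal transcription of the
    growth update that collapses the population; kept for comparison only).
    """
    n = np.asarray(n)
    if np.any(n < 0):
        raise ValueError("cell numbers must be non-negative")
    weighted = float(np.sum(n * np.exp(s_true)))
    if weighted == 0.0:
        return np.zeros_like(n, dtype=np.int64)
    if normalization == "relative":
        lam = 2.0 * n * np.exp(s_true) * (float(np.sum(n)) / weighted)
    elif normalization == "as_printed":
        lam = 2.0 * n * np.exp(s_true) / weighted
    else:
        raise ValueError("normalization must be 'relative' or 'as_printed'")
    return rng.poisson(lam).astype(np.int64)


def bottleneck_transfer(
    n_saturated: np.ndarray, g: int, rng: np.random.Generator
) -> np.ndarray:
    """Serial-dilution transfer: per lineage ``Pois(n_i / 2^g)``."""
    n_saturated = np.asarray(n_saturated)
    if np.any(n_saturated < 0):
        raise ValueError("cell numbers must be non-negative")
    return rng.poisson(n_saturated / 2.0**g).astype(np.int64)


def library_prep_and_sequence(
    n_population: np.ndarray,
    reads_per_lineage: float,
    n_dna_per_lineage: float,
    pcr_cycles: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """DNA extraction, PCR amplification, and sequencing as Poisson layers.

    Extraction draws an expected ``n_dna_per_lineage * L`` template copies
    allocated proportionally to lineage sizes; each PCR cycle replaces every
    template count ``t`` with ``t + Pois(t)``; sequencing draws an expected
    ``reads_per_lineage * L`` reads allocated proportionally to post-PCR
    copies.  A fully extinct population yields all-zero reads.
    """
    n_population = np.asarray(n_population, dtype=float)
    L = n_population.size
    total = n_population.sum()
    if total <= 0:
        return np.zeros(L, dtype=np.int64)
    dna = rng.poisson(n_dna_per_lineage * L * n_population / total).astype(np.int64)
    for _ in range(pcr_cycles):
        dna = dna + rng.poisson(dna)
    dna_total = float(dna.sum())
    if dna_total <= 0:
        return np.zeros(L, dtype=np.int64)
    reads = rng.poisson(reads_per_lineage * L * dna / dna_total)
    return reads.astype(np.int64)


def simulate_experiment(config: SimulationConfig) -> SimulationTruth:
    """Run the full multi-noise-layer experiment defined by ``config``.

    Returns the true fitnesses and initial cells, the bottleneck cell path at
    every sequenced time point, and the observed read matrix
    (``L x (T/g + 1)``).  Bit-identical output for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_lineages
    g = config.generations_per_cycle

    s_true = sample_fitness(
        config.dfe, L, rng,
        loc=config.dfe_loc, scale=config.dfe_scale, shape=config.dfe_shape,
    )
    if config.uniform_initial_cells is not None:
        n0 = np.full(L, int(round(config.uniform_initial_cells)), dtype=np.int64)
    else:
        n0 = sample_initial_cells(config.gamma_alpha, config.gamma_rate, L, rng)

    n_timepoints = config.n_cycles + 1
    cell_paths = np.zeros((L, n_timepoints), dtype=np.int64)
    read_matrix = np.zeros((L, n_timepoints), dtype=np.int64)

    cell_paths[:, 0] = n0
    read_matrix[:, 0] = library_prep_and_sequence(
        n0, config.reads_per_lineage, config.n_dna_per_lineage,
        config.pcr_cycles, rng,
    )

    n = n0.copy()
    for cycle in range(1, config.n_cycles + 1):
        for _ in range(g):
            n = grow_one_generation(n, s_true, rng, config.growth_normalization)
        read_matrix[:, cycle] = library_prep_and_sequence(
            n, config.reads_per_lineage, config.n_dna_per_lineage,
            config.pcr_cycles, rng,
        )
        n = bottleneck_transfer(n, g, rng)
        cell_paths[:, cycle] = n

    return SimulationTruth(
        s_true=s_true,
        n0_true=n0,
        cell_paths=cell_paths,
        read_matrix=read_matrix,
        time_points=config.time_points,
        config=config,
    )


def deterministic_reads(
    s_true: np.ndarray,
    n0_true: np.ndarray,
    time_points: np.ndarray,
    reads_per_lineage: float = 100.0,
    tol: float = 1e-13,
    max_iter: int = 500,
):
    """Noiseless, self-consistent read trajectories for known parameters.

    Builds real-valued cell paths that satisfy the likelihood's deterministic
    skeleton exactly: ``n_{i,k} = n_{i,k-1} E_k(s_i)`` with the growth factor
    evaluated under the trapezoid integral of the mean-fitness curve, where
    the curve itself is the fixed point of the read-frequency-weighted
    average ``s_bar(t_k) = sum_i s_i f_{i,k}``.  Reads are
    ``r_{i,k} = f_{i,k} R_k`` with ``R_k = reads_per_lineage * L``.

    Returns ``(reads, totals, N, sbar_values)``; inference on this input has
    a zero-objective optimum at the true parameters, which makes it the
    reference input for optimizer-correctness checks.
    """
    s_true = np.asarray(s_true, dtype=float)
    n0_true = np.asarray(n0_true, dtype=float)
    t = np.asarray(time_points, dtype=float)
    L = s_true.size
    K = t.size - 1
    dt = np.diff(t)

    sbar = np.zeros(K + 1)
    n = np.empty((L, K + 1))
    for _ in range(max_iter):
        n[:, 0] = n0_true
        for k in range(1, K + 1):
            integral = dt[k - 1] * (sbar[k - 1] + sbar[k]) / 2.0
            n[:, k] = n[:, k - 1] * np.exp(dt[k - 1] * s_true - integral)
        N = n.sum(axis=0)
        freqs = n / N
        new_sbar = freqs.T @ s_true
        if np.max(np.abs(new_sbar - sbar)) < tol:
            sbar = new_sbar
            break
        sbar = new_sbar
    n[:, 0] = n0_true
    for k in range(1, K + 1):
        integral = dt[k - 1] * (sbar[k - 1] + sbar[k]) / 2.0
        n[:, k] = n[:, k - 1] * np.exp(dt[k - 1] * s_true - integral)
    N = n.sum(axis=0)
    totals = np.full(K + 1, reads_per_lineage * L)
    reads = (n / N) * totals
    return reads, totals, N, sbar
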