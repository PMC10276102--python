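"""Branching-process likelihoods for barcode lineage trajectories.

A pooled competition assay follows ``L`` barcoded lineages through serial
batch culture.  At each sequencing time point ``t_k`` (in generations) a
lineage holds ``n_k`` cells at the bottleneck out of ``N_k`` total, and
receives ``r_k`` reads out of ``R_k`` total.  Two likelihoods of a single
lineage's read trajectory are provided:

* the joint likelihood of ``(s, n0)`` — Malthusian fitness and initial
  bottleneck cell number — built from square-root-scale Gaussian transition
  kernels for cell growth/transfer (noise ``c_k``) and for the sequencing
  pipeline (noise ``beta_k``), with the latent cell path integrated out by
  maximizing the integrand through a tridiagonal linear solve;
* the legacy read-to-read likelihood of ``s`` alone, a single
  branching-process kernel with noise ``kappa`` linking consecutive read
  counts.

Both use the growth factor ``E_k = exp[(t_k - t_{k-1}) s - int s_bar dt]``,
which discounts a lineage's expected frequency change by the population mean
fitness ``s_bar(t)`` (piecewise linear between sequenced time points).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeGrid",
    "ReadMatrix",
    "CellCensus",
    "NoiseParameters",
    "MeanFitnessCurve",
    "PathSolution",
    "DegenerateSystemError",
    "default_beta",
    "growth_factor",
    "growth_factors",
    "assemble_path_system",
    "solve_path",
    "neg_log_likelihood_v2",
    "neg_log_likelihood_v1",
]


class DegenerateSystemError(ValueError):
    """Raised when the tridiagonal path system has a vanishing pivot."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeGrid:
    """Sequencing time points ``t_0 < t_1 < ... < t_K`` in generations."""

    t: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time grid needs at least two time points")
        if not np.all(np.isfinite(t)):
            raise ValueError("time points must be finite")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time points must be strictly increasing")
        object.__setattr__(self, "t", t)

    @property
    def K(self) -> int:
        """Number of inter-sample intervals."""
        return self.t.size - 1

    @property
    def dt(self) -> np.ndarray:
        """Interval lengths ``t_k - t_{k-1}`` for ``k = 1..K``."""
        return np.diff(self.t)


@dataclass(frozen=True)
class ReadMatrix:
    """Lineage x time-point barcode read counts with derived totals.

    ``counts[i, k]`` is the read number of lineage ``i`` at time point
    ``t_k``.  ``totals`` are the per-time-point column sums ``R_k`` and
    ``freqs`` the read frequencies ``f_{i,k} = r_{i,k} / R_k``.
    """

    counts: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D lineage x time matrix")
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative read count at lineage {bad[0]}, time column {bad[1]}"
            )
        if not np.all(np.isfinite(np.asarray(counts, dtype=float))):
            raise ValueError("read counts must be finite")
        object.__setattr__(self, "counts", counts)
        ids = self.ids
        if ids is None:
            ids = np.arange(counts.shape[0])
        else:
            ids = np.asarray(ids)
            if ids.size != counts.shape[0]:
                raise ValueError("ids length must match number of lineages")
        object.__setattr__(self, "ids", ids)

    @property
    def n_lineages(self) -> int:
        return self.counts.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.counts.shape[1]

    @property
    def totals(self) -> np.ndarray:
        """Per-time-point total read depth ``R_k``."""
        return self.counts.sum(axis=0).astype(float)

    @property
    def freqs(self) -> np.ndarray:
        """Read frequencies ``f_{i,k}``; zero where a column total is zero."""
        totals = self.totals
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(totals > 0, self.counts / totals, 0.0)
        return f


@dataclass(frozen=True)
class CellCensus:
    """Total bottleneck cell numbers ``N_k`` and per-lineage mean ``n_bar``."""

    N: np.ndarray
    n_bar: np.ndarray

    def __post_init__(self) -> None:
        N = np.atleast_1d(np.asarray(self.N, dtype=float))
        n_bar = np.atleast_1d(np.asarray(self.n_bar, dtype=float))
        if np.any(N <= 0) or np.any(n_bar <= 0):
            raise ValueError("bottleneck cell numbers must be positive")
        object.__setattr__(self, "N", N)
        object.__setattr__(self, "n_bar", n_bar)

    @classmethod
    def from_cells_per_lineage(
        cls, n_bar: float, n_lineages: int, n_timepoints: int
    ) -> "CellCensus":
        """Expand a single per-lineage bottleneck size as ``N_k = n_bar * L``."""
        N = np.full(n_timepoints, float(n_bar) * n_lineages)
        return cls(N=N, n_bar=np.full(n_timepoints, float(n_bar)))

    @classmethod
    def from_total_cells(cls, N, n_lineages: int) -> "CellCensus":
        N = np.atleast_1d(np.asarray(N, dtype=float))
        return cls(N=N, n_bar=N / n_lineages)


@dataclass(frozen=True)
class NoiseParameters:
    """Noise scales of the transition kernels.

    ``c``  — per-interval growth/transfer noise (half the per-individual
    offspring-number variance per growth cycle; default 1, i.e. variance 2).
    ``beta`` — per-time-point read noise (half the per-read variance of the
    DNA-extraction / PCR / sequencing pipeline).
    ``kappa`` — the legacy single-layer read-to-read noise scale.
    """

    c: np.ndarray
    beta: np.ndarray
    kappa: float = 2.5
    n_dna: float = 500.0
    r_bar: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.atleast_1d(np.asarray(self.c, dtype=float))
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if np.any(c <= 0) or np.any(beta <= 0):
            raise ValueError("noise parameters c and beta must be positive")
        if not (self.kappa > 0):
            raise ValueError("kappa must be positive")
        if not (self.n_dna > 0):
            raise ValueError("n_dna must be positive")
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "beta", beta)

    @classmethod
    def with_defaults(
        cls,
        grid: TimeGrid,
        census: CellCensus,
        totals: np.ndarray,
        n_lineages: int,
        c: float | np.ndarray = 1.0,
        beta: float | np.ndarray | None = None,
        kappa: float = 2.5,
        n_dna: float = 500.0,
    ) -> "NoiseParameters":
        """Fill per-time-point defaults from the experimental design.

        ``beta`` defaults to :func:`default_beta` evaluated per time point at
        the observed mean read depth ``r_bar_k = R_k / L`` and the census
        ``n_bar_k``; ``c`` defaults to 1 everywhere.
        """
        K = grid.K
        c_arr = np.broadcast_to(np.asarray(c, dtype=float), (K,)).copy()
        r_bar = np.asarray(totals, dtype=float) / n_lineages
        n_bar = np.broadcast_to(census.n_bar, (K + 1,))
        if beta is None:
            beta_arr = default_beta(r_bar, n_bar, n_dna)
        else:
            beta_arr = np.broadcast_to(np.asarray(beta, dtype=float), (K + 1,)).copy()
        return cls(c=c_arr, beta=beta_arr, kappa=kappa, n_dna=n_dna, r_bar=r_bar)


@dataclass(frozen=True)
class MeanFitnessCurve:
    """Population mean fitness ``s_bar(t)``, linear between sequenced points."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.t.shape:
            raise ValueError("one mean-fitness value per grid point required")
        if not np.all(np.isfinite(values)):
            raise ValueError("mean fitness values must be finite")
        object.__setattr__(self, "values", values)

    @classmethod
    def zero(cls, grid: TimeGrid) -> "MeanFitnessCurve":
        return cls(grid=grid, values=np.zeros_like(grid.t))

    def __call__(self, t) -> np.ndarray | float:
        return np.interp(t, self.grid.t, self.values)

    def interval_integral(self, k: int) -> float:
        """Exact ``int s_bar dt`` over ``[t_{k-1}, t_k]`` (trapezoid rule,
        which is exact for the piecewise-linear curve)."""
        if not 1 <= k <= self.grid.K:
            raise ValueError(f"interval index k={k} outside 1..{self.grid.K}")
        dt = self.grid.t[k] - self.grid.t[k - 1]
        return dt * (self.values[k - 1] + self.values[k]) / 2.0

    def interval_integrals(self) -> np.ndarray:
        """All ``K`` interval integrals at once."""
        return self.grid.dt * (self.values[:-1] + self.values[1:]) / 2.0


@dataclass(frozen=True)
class PathSolution:
    """Maximum-of-integrand latent cell path on the square-root scale."""

    nu: np.ndarray
    clamped: bool = False

    @property
    def n(self) -> np.ndarray:
        """Implied bottleneck cell numbers ``n_k = nu_k**2`` for ``k=1..K``."""
        return self.nu**2


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def default_beta(r_bar, n_bar, n_dna):
    """Per-read noise scale ``beta`` implied by the sequencing pipeline.

    ``2 * beta`` is the per-read variance accumulated over reverse dilution
    (``r_bar / n_bar``), genomic DNA extraction and PCR (``r_bar / n_dna``
    each), and sequencing itself (1):

        beta = (r_bar / n_bar + 2 * r_bar / n_dna + 1) / 2

    Parameters are the average reads, bottleneck cells, and genomic DNA
    copies per lineage; all must be positive.
    """
    r_bar = np.asarray(r_bar, dtype=float)
    n_bar = np.asarray(n_bar, dtype=float)
    n_dna = np.asarray(n_dna, dtype=float)
    if np.any(r_bar <= 0) or np.any(n_bar <= 0) or np.any(n_dna <= 0):
        raise ValueError("default_beta arguments must be strictly positive")
    out = (r_bar / n_bar + 2.0 * r_bar / n_dna + 1.0) / 2.0
    return float(out) if out.ndim == 0 else out


def growth_factor(s: float, k: int, sbar: MeanFitnessCurve, grid: TimeGrid) -> float:
    """Expected frequency fold-change ``E_k`` of a lineage over interval ``k``.

    ``E_k = exp[(t_k - t_{k-1}) s - int_{t_{k-1}}^{t_k} s_bar(t) dt]``: growth
    at the lineage's own rate, discounted by the population mean fitness.  A
    lineage at the mean has ``E_k = 1`` (flat expected frequency).
    """
    if not np.isfinite(s):
        raise ValueError("fitness s must be finite")
    if not 1 <= k <= grid.K:
        raise ValueError(f"interval index k={k} outside 1..{grid.K}")
    dt = grid.t[k] - grid.t[k - 1]
    return math.exp(dt * s - sbar.interval_integral(k))


def growth_factors(s: float, sbar: MeanFitnessCurve, grid: TimeGrid) -> np.ndarray:
    """All ``K`` growth factors ``E_1..E_K`` for one lineage."""
    if not np.isfinite(s):
        raise ValueError("fitness s must be finite")
    return np.exp(grid.dt * s - sbar.interval_integrals())


def assemble_path_system(E, c, beta, rho, gamma_sqrt, nu0: float):
    """Build the tridiagonal system whose solution maximizes the path integrand.

    All arguments are indexed by interval/time point ``k = 1..K`` (length
    ``K`` each; scalars broadcast): growth factors ``E_k``, noise scales
    ``c_k`` and ``beta_k``, sampling ratios ``rho_k = sqrt(R_k / N_k)`` and
    observed ``gamma_k = sqrt(r_k)``.  ``nu0 = sqrt(n0)`` enters the first
    right-hand-side entry.

    Returns ``(m, b)`` with ``m`` the dense ``K x K`` tridiagonal matrix
    (symmetric, positive definite for valid inputs) and ``b`` the RHS.
    """
    E = np.atleast_1d(np.asarray(E, dtype=float))
    K = E.size
    if K == 0:
        raise ValueError("at least one interval is required (K >= 1)")
    c = np.broadcast_to(np.asarray(c, dtype=float), (K,))
    beta = np.broadcast_to(np.asarray(beta, dtype=float), (K,))
    rho = np.broadcast_to(np.asarray(rho, dtype=float), (K,))
    gamma_sqrt = np.broadcast_to(np.asarray(gamma_sqrt, dtype=float), (K,))
    for name, arr in (("E", E), ("c", c), ("beta", beta), ("rho", rho)):
        if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} entries must be finite and positive")
    if np.any(gamma_sqrt < 0) or not np.all(np.isfinite(gamma_sqrt)):
        raise ValueError("gamma entries must be finite and non-negative")
    if not (np.isfinite(nu0) and nu0 >= 0):
        raise ValueError("nu0 must be finite and non-negative")

    sqrtE = np.sqrt(E)
    diag = 1.0 / c + rho**2 / beta
    diag[:-1] += E[1:] / c[1:]
    off = -sqrtE[1:] / c[1:]  # couples nu_k and nu_{k+1}

    m = np.diag(diag)
    if K > 1:
        m[np.arange(K - 1), np.arange(1, K)] = off
        m[np.arange(1, K), np.arange(K - 1)] = off
    b = rho * gamma_sqrt / beta
    b = b.copy()
    b[0] += sqrtE[0] * nu0 / c[0]
    return m, b


def solve_path(m: np.ndarray, b: np.ndarray) -> PathSolution:
    """Solve the tridiagonal path system by the Thomas algorithm.

    Returns the square-root cell path ``nu_1..nu_K``; any negative component
    (possible for near-extinct lineages) is clamped to 0 and flagged, since
    ``nu = sqrt(n)`` must be non-negative.  A vanishing pivot raises
    :class:`DegenerateSystemError`.
    """
    m = np.asarray(m, dtype=float)
    b = np.asarray(b, dtype=float)
    K = b.size
    diag = np.diagonal(m).copy()
    upper = np.diagonal(m, offset=1).copy() if K > 1 else np.empty(0)
    lower = np.diagonal(m, offset=-1).copy() if K > 1 else np.empty(0)

    # forward elimination
    cp = np.empty(max(K - 1, 0))
    dp = np.empty(K)
    piv = diag[0]
    if piv == 0.0:
        raise DegenerateSystemError("zero pivot in tridiagonal solve")
    if K > 1:
        cp[0] = upper[0] / piv
    dp[0] = b[0] / piv
    for k in range(1, K):
        piv = diag[k] - lower[k - 1] * cp[k - 1]
        if piv == 0.0:
            raise DegenerateSystemError("zero pivot in tridiagonal solve")
        if k < K - 1:
            cp[k] = upper[k] / piv
        dp[k] = (b[k] - lower[k - 1] * dp[k - 1]) / piv
    # back substitution
    nu = np.empty(K)
    nu[K - 1] = dp[K - 1]
    for k in range(K - 2, -1, -1):
        nu[k] = dp[k] - cp[k] * nu[k + 1]

    clamped = bool(np.any(nu < 0))
    if clamped:
        nu = np.maximum(nu, 0.0)
    return PathSolution(nu=nu, clamped=clamped)


def _path_objective(nu, nu0, sqrtE, c, beta, rho, gamma_sqrt) -> float:
    """Negative exponent of the path integrand at a given nu path (k=1..K)."""
    nu_prev = np.concatenate(([nu0], nu[:-1]))
    growth = (nu - sqrtE * nu_prev) ** 2 / c
    seq = (rho * nu - gamma_sqrt) ** 2 / beta
    return float(np.sum(growth) + np.sum(seq))


def neg_log_likelihood_v2(
    s: float,
    n0: float,
    reads: np.ndarray,
    totals: np.ndarray,
    census: CellCensus,
    sbar: MeanFitnessCurve,
    noise: NoiseParameters,
    grid: TimeGrid,
    return_path: bool = False,
):
    """Joint negative log-likelihood of ``(s, n0)`` for one lineage.

    Exponent-only form: the Gaussian square-root-scale kernels enter without
    their normalizing prefactors, so the value is a negative log-likelihood
    up to an additive constant.  The latent cell path is integrated out by
    the maximum-of-integrand approximation (tridiagonal solve).  The read
    term at ``t_0``, ``(sqrt(r_0) - sqrt(n0 R_0 / N_0))**2 / beta_0``, ties
    ``n0`` to the first observation.

    Zero on a noiseless self-consistent trajectory; non-negative always.
    With ``return_path=True`` also returns the :class:`PathSolution`.
    """
    if not (np.isfinite(s) and np.isfinite(n0)):
        raise ValueError("s and n0 must be finite")
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    reads = np.asarray(reads, dtype=float)
    totals = np.asarray(totals, dtype=float)
    K = grid.K
    if reads.size != K + 1 or totals.size != K + 1:
        raise ValueError("reads and totals must have K+1 entries")
    if np.any(reads < 0):
        raise ValueError("reads must be non-negative")

    N = np.broadcast_to(census.N, (K + 1,))
    rho = np.sqrt(totals / N)
    gamma = np.sqrt(reads)
    nu0 = math.sqrt(n0)
    E = growth_factors(s, sbar, grid)
    c = np.broadcast_to(noise.c, (K,))
    beta = np.broadcast_to(noise.beta, (K + 1,))

    m, b = assemble_path_system(E, c, beta[1:], rho[1:], gamma[1:], nu0)
    path = solve_path(m, b)
    obj = _path_objective(path.nu, nu0, np.sqrt(E), c, beta[1:], rho[1:], gamma[1:])
    obj += (gamma[0] - rho[0] * nu0) ** 2 / beta[0]
    if return_path:
        return obj, path
    return obj


def neg_log_likelihood_v1(
    s: float,
    reads: np.ndarray,
    totals: np.ndarray,
    sbar: MeanFitnessCurve,
    noise: NoiseParameters,
    grid: TimeGrid,
) -> float:
    """Legacy read-to-read negative log-likelihood of ``s`` for one lineage.

    Full-density form of the branching-process kernel linking consecutive
    read counts, with noise scale ``kappa`` (half the per-read variance):

        p(r_k | r_{k-1}, s) = sqrt(mu_k^{1/2} / (4 pi kappa r_k^{3/2}))
                              * exp[-(sqrt(r_k) - sqrt(mu_k))**2 / kappa]

    with ``mu_k = r_{k-1} E_k R_k / R_{k-1}``.  Because ``r_k^{3/2}`` and
    ``mu_k`` sit in the density, any zero read count along the trajectory
    makes it undefined; such lineages get the sentinel ``nan`` (their
    fitness should come from the joint likelihood instead).
    """
    if not np.isfinite(s):
        raise ValueError("fitness s must be finite")
    reads = np.asarray(reads, dtype=float)
    totals = np.asarray(totals, dtype=float)
    K = grid.K
    if reads.size != K + 1 or totals.size != K + 1:
        raise ValueError("reads and totals must have K+1 entries")
    if np.any(reads == 0):
        return math.nan
    kappa = noise.kappa
    E = growth_factors(s, sbar, grid)
    mu = reads[:-1] * E * totals[1:] / totals[:-1]
    # -log prefactor = -(1/4) log mu + (1/2) log(4 pi kappa) + (3/4) log r_k
    neg_log_pref = (
        -0.25 * np.log(mu)
        + 0.5 * math.log(4.0 * math.pi * kappa)
        + 0.75 * np.log(reads[1:])
    )
    expo = (np.sqrt(reads[1:]) - np.sqrt(mu)) ** 2 / kappa
    return float(np.sum(neg_log_pref + expo))


# ---------------------------------------------------------------------------
# Vectorized evaluation over optimizer populations
# ---------------------------------------------------------------------------


@dataclass
class LikelihoodContext:
    """Shared per-dataset quantities for fast batched likelihood evaluation.

    Everything except the lineage's own reads is common to all lineages:
    interval lengths, the mean-fitness integral per interval, sampling ratios
    ``rho_k``, and the noise scales.  ``nll_batch`` evaluates the joint
    negative log-likelihood at a population of ``(s, n0)`` candidates for a
    single lineage in one vectorized pass (Thomas algorithm unrolled over
    intervals, vectorized over candidates).
    """

    grid: TimeGrid
    census: CellCensus
    noise: NoiseParameters
    totals: np.ndarray
    sbar_integrals: np.ndarray = field(init=False)
    rho: np.ndarray = field(init=False)
    c: np.ndarray = field(init=False)
    beta: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        K = self.grid.K
        totals = np.asarray(self.totals, dtype=float)
        N = np.broadcast_to(self.census.N, (K + 1,))
        self.rho = np.sqrt(totals / N)
        self.sbar_integrals = np.zeros(K)
        self.c = np.broadcast_to(self.noise.c, (K,)).astype(float)
        self.beta = np.broadcast_to(self.noise.beta, (K + 1,)).astype(float)

    def set_mean_fitness(self, sbar: MeanFitnessCurve) -> None:
        self.sbar_integrals = sbar.interval_integrals()

    def nll_batch(self, gamma: np.ndarray, s: np.ndarray, n0: np.ndarray) -> np.ndarray:
        """Joint NLL at S candidate parameter pairs for one lineage.

        ``gamma`` is the lineage's ``sqrt(r_k)`` (length K+1); ``s`` and
        ``n0`` are candidate vectors of equal length S.
        """
        grid = self.grid
        K = grid.K
        c = self.c
        beta = self.beta
        rho = self.rho
        s = np.atleast_1d(np.asarray(s, dtype=float))
        n0 = np.atleast_1d(np.asarray(n0, dtype=float))
        S = s.size

        # growth factors per interval per candidate: (K, S)
        logE = grid.dt[:, None] * s[None, :] - self.sbar_integrals[:, None]
        E = np.exp(logE)
        sqrtE = np.exp(0.5 * logE)
        nu0 = np.sqrt(n0)

        diag = np.empty((K, S))
        diag[:] = (1.0 / c + rho[1:] ** 2 / beta[1:])[:, None]
        if K > 1:
            diag[:-1] += E[1:] / c[1:, None]
        b = np.empty((K, S))
        b[:] = (rho[1:] * gamma[1:] / beta[1:])[:, None]
        b[0] += sqrtE[0] * nu0 / c[0]
        # off-diagonal couplings between nu_k and nu_{k+1}: (K-1, S)
        off = -sqrtE[1:] / c[1:, None]

        # Thomas algorithm, vectorized over candidates
        cp = np.empty((max(K - 1, 0), S))
        dp = np.empty((K, S))
        piv = diag[0]
        if K > 1:
            cp[0] = off[0] / piv
        dp[0] = b[0] / piv
        for k in range(1, K):
            piv = diag[k] - off[k - 1] * cp[k - 1]
            if k < K - 1:
                cp[k] = off[k] / piv
            dp[k] = (b[k] - off[k - 1] * dp[k - 1]) / piv
        nu = np.empty((K, S))
        nu[K - 1] = dp[K - 1]
        for k in range(K - 2, -1, -1):
            nu[k] = dp[k] - cp[k] * nu[k + 1]
        np.maximum(nu, 0.0, out=nu)

        nu_prev = np.vstack([nu0[None, :], nu[:-1]])
        growth = (nu - sqrtE * nu_prev) ** 2 / c[:, None]
        seq = (rho[1:, None] * nu - gamma[1:, None]) ** 2 / beta[1:, None]
        obj = growth.sum(axis=0) + seq.sum(axis=0)
        obj += (gamma[0] - rho[0] * nu0) ** 2 / beta[0]
        return obj
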