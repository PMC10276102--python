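"""Iterative per-lineage fitness estimation for pooled competition assays.

The estimation problem is self-referential: each lineage's likelihood depends
on the population mean fitness ``s_bar(t)``, which in turn is the
read-frequency-weighted average of all lineage fitnesses.  The engine
alternates between (a) optimizing each lineage's parameters under the
current mean-fitness curve and (b) recomputing the curve from the new
estimates, until the summed objective stops improving.

Two likelihood modes are supported (see :mod:`barseqfit.likelihood`):

* ``"joint"`` — per-lineage global optimization of ``(s, n0)`` by
  differential evolution (gradient-free, bound-constrained), starting from a
  zero mean-fitness curve;
* ``"legacy"`` — one-dimensional optimization of ``s`` under the read-to-read
  kernel, starting from a log-linear-regression mean-fitness curve.

The public surface is the scikit-learn style :class:`FitnessEstimator`;
:func:`run_inference` is a thin functional wrapper around it.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from scipy.optimize import differential_evolution, minimize, minimize_scalar
from sklearn.base import BaseEstimator

from .likelihood import (
    CellCensus,
    LikelihoodContext,
    MeanFitnessCurve,
    NoiseParameters,
    ReadMatrix,
    TimeGrid,
    growth_factors,
    neg_log_likelihood_v1,
    neg_log_likelihood_v2,
)

__all__ = [
    "LineageEstimate",
    "FitResult",
    "FitnessEstimator",
    "init_mean_fitness_v2",
    "init_mean_fitness_v1",
    "update_mean_fitness",
    "estimate_lineage",
    "run_inference",
    "reconstruct_trajectory",
]


# ---------------------------------------------------------------------------
# Mean-fitness curve construction and update
# ---------------------------------------------------------------------------


def init_mean_fitness_v2(grid: TimeGrid) -> MeanFitnessCurve:
    """Initial mean-fitness curve for the joint mode: identically zero."""
    return MeanFitnessCurve.zero(grid)


def init_mean_fitness_v1(reads: ReadMatrix, grid: TimeGrid) -> MeanFitnessCurve:
    """Initial mean fitness for the legacy mode by log-linear regression.

    Each lineage with positive counts at the first two time points gets the
    slope ``(log f_{i,1} - log f_{i,0}) / (t_1 - t_0)``; lineages without
    both counts contribute slope 0.  The slopes are combined into
    ``s_bar(t_k)`` with the read-frequency weights at each time point.
    """
    counts = reads.counts
    totals = reads.totals
    if totals[0] <= 0 or totals[1] <= 0:
        raise ValueError("first two time points must have positive total reads")
    f = reads.freqs
    pos = (counts[:, 0] > 0) & (counts[:, 1] > 0)
    if not np.any(pos):
        raise ValueError("no lineage has positive reads at both t0 and t1")
    dt = grid.t[1] - grid.t[0]
    slopes = np.zeros(reads.n_lineages)
    slopes[pos] = (np.log(f[pos, 1]) - np.log(f[pos, 0])) / dt
    values = f.T @ slopes
    return MeanFitnessCurve(grid=grid, values=values)


def update_mean_fitness(s_hats: np.ndarray, reads: ReadMatrix) -> MeanFitnessCurve:
    """Read-frequency-weighted mean fitness ``s_bar(t_k) = sum_i s_i f_{i,k}``.

    Lineages with a ``nan`` fitness (legacy sentinel for zero-read
    trajectories) contribute zero to the weighted sum.
    """
    s_hats = np.asarray(s_hats, dtype=float)
    if s_hats.size != reads.n_lineages:
        raise ValueError("one fitness per lineage is required")
    s_filled = np.where(np.isfinite(s_hats), s_hats, 0.0)
    grid = TimeGrid(np.arange(reads.n_timepoints, dtype=float))
    values = reads.freqs.T @ s_filled
    return MeanFitnessCurve(grid=grid, values=values)


def _weighted_mean_fitness(
    s_hats: np.ndarray, freqs: np.ndarray, grid: TimeGrid
) -> MeanFitnessCurve:
    s_filled = np.where(np.isfinite(s_hats), s_hats, 0.0)
    return MeanFitnessCurve(grid=grid, values=freqs.T @ s_filled)


def _fix_gauge(s_arr, sbar, freqs, grid):
    """Anchor the fitness gauge at the first time point.

    The likelihood depends on ``s`` only through ``s - s_bar`` (the growth
    factor), so shifting every lineage fitness and the mean-fitness curve by
    the same constant leaves every objective value unchanged — the iterative
    procedure alone cannot fix the absolute scale.  Fitness is defined
    relative to the initial population, whose mean fitness is zero by
    convention, so the shift is chosen to make
    ``s_bar(t_0) = sum_i s_i f_{i,0} = 0``.  Returns the re-gauged estimates
    and the matching shifted curve.
    """
    s_filled = np.where(np.isfinite(s_arr), s_arr, 0.0)
    delta = float(freqs[:, 0] @ s_filled)
    s_out = np.where(np.isfinite(s_arr), s_arr - delta, s_arr)
    sbar_out = MeanFitnessCurve(grid=grid, values=sbar.values - delta)
    return s_out, sbar_out


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LineageEstimate:
    """Optimized parameters and reconstruction for a single lineage."""

    lineage_id: object
    s_hat: float
    n0_hat: float
    objective: float
    n_path: np.ndarray
    r_hat: np.ndarray
    flags: tuple[str, ...] = ()


@dataclass
class FitResult:
    """Outcome of the iterative estimation over all lineages."""

    ids: np.ndarray
    s_hat: np.ndarray
    n0_hat: np.ndarray
    objective: np.ndarray
    n_path: np.ndarray
    reads_hat: np.ndarray
    flags: list[tuple[str, ...]]
    mean_fitness: MeanFitnessCurve
    iterations: int
    total_objective: list[float] = field(default_factory=list)
    method: str = "joint"
    converged: bool = True
    seed: int | None = None
    #: curve the accepted estimates were optimized under (same gauge); the
    #: public ``mean_fitness`` is its one-step update from the final fitnesses
    sbar_fit: MeanFitnessCurve | None = None

    @property
    def estimates(self) -> list[LineageEstimate]:
        return [
            LineageEstimate(
                lineage_id=self.ids[i],
                s_hat=float(self.s_hat[i]),
                n0_hat=float(self.n0_hat[i]),
                objective=float(self.objective[i]),
                n_path=self.n_path[i],
                r_hat=self.reads_hat[i],
                flags=self.flags[i],
            )
            for i in range(self.ids.size)
        ]

    def to_frame(self):
        """Per-lineage estimates as a pandas DataFrame."""
        import pandas as pd

        K1 = self.reads_hat.shape[1]
        t = self.mean_fitness.grid.t
        data = {
            "lineage": self.ids,
            "s_hat": self.s_hat,
            "n0_hat": self.n0_hat,
            "objective": self.objective,
            "flags": [";".join(f) for f in self.flags],
        }
        for k in range(K1):
            data[f"r_hat_t{t[k]:g}"] = self.reads_hat[:, k]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Per-lineage optimization
# ---------------------------------------------------------------------------


def _lineage_seed(master_seed: int, lineage_id) -> np.random.SeedSequence:
    """Reproducible per-lineage seed, stable under reordering (keyed by id)."""
    key = zlib.crc32(str(lineage_id).encode())
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key])


def _naive_n0(reads_row, totals, N, sbar_integrals, dt) -> tuple[float, bool]:
    """Plug-in initial cell number ``r_0 N_0 / R_0``.

    If ``r_0 = 0``, the first nonzero time point is mapped back through the
    neutral growth factors; all-zero rows fall back to a small floor.
    """
    nz = np.nonzero(reads_row)[0]
    if nz.size == 0:
        return 0.1, True
    j = nz[0]
    n_j = reads_row[j] * N[j] / totals[j]
    if j == 0:
        return float(n_j), False
    logE = -sbar_integrals[:j]  # s = 0 surrogate
    return float(n_j / np.exp(np.sum(logE))), False


def _de_objective(ctx: LikelihoodContext, gamma: np.ndarray):
    def fun(x):
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            return float(ctx.nll_batch(gamma, x[:1], np.exp(x[1:2]))[0])
        return ctx.nll_batch(gamma, x[0], np.exp(x[1]))

    return fun


def _optimize_joint_de(
    ctx: LikelihoodContext,
    reads_row: np.ndarray,
    totals: np.ndarray,
    s_bounds: tuple[float, float],
    n0_bound_factor: float,
    seed_seq: np.random.SeedSequence,
    de_opts: dict,
) -> tuple[float, float, float, bool]:
    """Global (s, log n0) search for one lineage; returns s, n0, obj, flag."""
    gamma = np.sqrt(reads_row)
    N = np.broadcast_to(ctx.census.N, (ctx.grid.K + 1,))
    n0_tilde, allzero = _naive_n0(
        reads_row, totals, N, ctx.sbar_integrals, ctx.grid.dt
    )
    lo = max(n0_tilde / n0_bound_factor, 0.1)
    hi = max(n0_tilde * n0_bound_factor, 1.0)
    bounds = [s_bounds, (np.log(lo), np.log(hi))]
    fun = _de_objective(ctx, gamma)
    rng = np.random.default_rng(seed_seq)
    res = differential_evolution(
        fun,
        bounds=bounds,
        strategy=de_opts["strategy"],
        popsize=de_opts["popsize"],
        maxiter=de_opts["maxiter"],
        tol=de_opts["tol"],
        mutation=de_opts["mutation"],
        recombination=de_opts["recombination"],
        seed=rng,
        polish=de_opts["polish"],
        init="latinhypercube",
        updating="deferred",
        vectorized=True,
    )
    return float(res.x[0]), float(np.exp(res.x[1])), float(res.fun), not res.success


def _refine_joint(
    ctx: LikelihoodContext,
    reads_row: np.ndarray,
    s_bounds: tuple[float, float],
    x0: tuple[float, float],
) -> tuple[float, float, float, bool]:
    """Local refinement from a previous optimum after a mean-fitness update."""
    gamma = np.sqrt(reads_row)
    fun = _de_objective(ctx, gamma)
    x0 = np.array([x0[0], np.log(x0[1])])
    res = minimize(
        fun,
        x0,
        method="L-BFGS-B",
        bounds=[s_bounds, (x0[1] - np.log(50.0), x0[1] + np.log(50.0))],
    )
    return float(res.x[0]), float(np.exp(res.x[1])), float(res.fun), False


def _optimize_legacy(
    reads_row: np.ndarray,
    totals: np.ndarray,
    sbar: MeanFitnessCurve,
    noise: NoiseParameters,
    grid: TimeGrid,
    s_bounds: tuple[float, float],
) -> tuple[float, float, bool]:
    """Bounded 1-D minimization of the legacy likelihood; nan on zero reads."""
    if np.any(reads_row == 0):
        return np.nan, np.nan, True
    res = minimize_scalar(
        lambda s: neg_log_likelihood_v1(s, reads_row, totals, sbar, noise, grid),
        bounds=s_bounds,
        method="bounded",
        options={"xatol": 1e-7},
    )
    return float(res.x), float(res.fun), False


def estimate_lineage(
    reads_row: np.ndarray,
    totals: np.ndarray,
    census: CellCensus,
    sbar: MeanFitnessCurve,
    noise: NoiseParameters,
    grid: TimeGrid,
    bounds: tuple | None = None,
    n0_bound_factor: float = 50.0,
    seed: int = 0,
    lineage_id=0,
    **de_overrides,
) -> LineageEstimate:
    """Estimate one lineage's ``(s, n0)`` by differential evolution.

    The fitness box defaults to ``[-1, 1]``; the initial-cell box is
    multiplicative around the plug-in ``n0 = r_0 N_0 / R_0`` (searched on the
    log scale).  Deterministic for a fixed ``seed``/``lineage_id`` pair.
    """
    reads_row = np.asarray(reads_row, dtype=float)
    totals = np.asarray(totals, dtype=float)
    ctx = LikelihoodContext(grid=grid, census=census, noise=noise, totals=totals)
    ctx.set_mean_fitness(sbar)
    de_opts = dict(_DEFAULT_DE_OPTS)
    de_opts.update(de_overrides)
    s_bounds = bounds[0] if bounds is not None else (-1.0, 1.0)
    if bounds is not None and len(bounds) > 1 and bounds[1] is not None:
        n0_lo, n0_hi = bounds[1]
        gamma = np.sqrt(reads_row)
        fun = _de_objective(ctx, gamma)
        rng = np.random.default_rng(_lineage_seed(seed, lineage_id))
        res = differential_evolution(
            fun,
            bounds=[s_bounds, (np.log(n0_lo), np.log(n0_hi))],
            strategy=de_opts["strategy"],
            popsize=de_opts["popsize"],
            maxiter=de_opts["maxiter"],
            tol=de_opts["tol"],
            mutation=de_opts["mutation"],
            recombination=de_opts["recombination"],
            seed=rng,
            polish=de_opts["polish"],
            init="latinhypercube",
            updating="deferred",
            vectorized=True,
        )
        s_hat, n0_hat, obj, flag = (
            float(res.x[0]),
            float(np.exp(res.x[1])),
            float(res.fun),
            not res.success,
        )
    else:
        s_hat, n0_hat, obj, flag = _optimize_joint_de(
            ctx,
            reads_row,
            totals,
            s_bounds,
            n0_bound_factor,
            _lineage_seed(seed, lineage_id),
            de_opts,
        )
    return _finalize_joint(
        lineage_id, s_hat, n0_hat, obj, flag, reads_row, totals, census, sbar, noise, grid
    )


_DEFAULT_DE_OPTS = {
    "strategy": "best1bin",
    "popsize": 15,
    "maxiter": 120,
    "tol": 1e-3,
    "mutation": (0.5, 1.0),
    "recombination": 0.7,
    "polish": True,
}


def _finalize_joint(
    lineage_id, s_hat, n0_hat, obj, maxiter_flag, reads_row, totals, census, sbar, noise, grid
) -> LineageEstimate:
    _, path = neg_log_likelihood_v2(
        s_hat, n0_hat, reads_row, totals, census, sbar, noise, grid, return_path=True
    )
    N = np.broadcast_to(census.N, (grid.K + 1,))
    n_full = np.concatenate(([n0_hat], path.n))
    r_hat = n_full * totals / N
    flags = []
    if path.clamped:
        flags.append("clamped")
    if maxiter_flag:
        flags.append("optimizer_budget")
    return LineageEstimate(
        lineage_id=lineage_id,
        s_hat=s_hat,
        n0_hat=n0_hat,
        objective=obj,
        n_path=path.n,
        r_hat=r_hat,
        flags=tuple(flags),
    )


def reconstruct_trajectory(
    est: LineageEstimate,
    reads_row: np.ndarray,
    totals: np.ndarray,
    census: CellCensus | None,
    sbar: MeanFitnessCurve,
    grid: TimeGrid,
    method: str = "joint",
) -> np.ndarray:
    """Reconstructed read trajectory ``r_hat_0..r_hat_K`` for one lineage.

    Joint mode maps the implied cell path through the sampling ratio,
    ``r_hat_k = n_k R_k / N_k``; legacy mode propagates the observed previous
    read through the growth factor, ``r_hat_k = r_{k-1} E_k R_k / R_{k-1}``
    with ``r_hat_0 = r_0``.
    """
    totals = np.asarray(totals, dtype=float)
    if method == "joint":
        if census is None:
            raise ValueError("joint reconstruction requires a cell census")
        N = np.broadcast_to(census.N, (grid.K + 1,))
        n_full = np.concatenate(([est.n0_hat], est.n_path))
        return n_full * totals / N
    elif method == "legacy":
        reads_row = np.asarray(reads_row, dtype=float)
        E = growth_factors(est.s_hat, sbar, grid)
        r_hat = np.empty(grid.K + 1)
        r_hat[0] = reads_row[0]
        r_hat[1:] = reads_row[:-1] * E * totals[1:] / totals[:-1]
        return r_hat
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Parallel worker chunks (module-level for picklability)
# ---------------------------------------------------------------------------


def _joint_de_chunk(ctx, counts, totals, idx, ids, s_bounds, factor, master_seed, de_opts):
    out = []
    for i in idx:
        out.append(
            _optimize_joint_de(
                ctx,
                counts[i].astype(float),
                totals,
                s_bounds,
                factor,
                _lineage_seed(master_seed, ids[i]),
                de_opts,
            )
        )
    return out


def _joint_refine_chunk(ctx, counts, idx, s_bounds, x0s):
    out = []
    for j, i in enumerate(idx):
        out.append(_refine_joint(ctx, counts[i].astype(float), s_bounds, x0s[j]))
    return out


def _legacy_chunk(counts, totals, idx, sbar, noise, grid, s_bounds):
    out = []
    for i in idx:
        out.append(
            _optimize_legacy(counts[i].astype(float), totals, sbar, noise, grid, s_bounds)
        )
    return out


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class FitnessEstimator(BaseEstimator):
    """Per-lineage Malthusian fitness (and initial cell number) estimator.

    Fits the iterative mean-fitness / per-lineage-likelihood procedure to a
    lineage x time-point barcode read-count matrix.

    Parameters
    ----------
    method : {"joint", "legacy"}
        ``"joint"`` optimizes ``(s, n0)`` per lineage under the latent
        cell-path likelihood (differential evolution); ``"legacy"`` optimizes
        ``s`` alone under the read-to-read kernel.
    time_points : sequence of float or None
        Sequencing times in generations.  May be omitted when ``X`` is a
        DataFrame whose column labels parse as times (e.g. ``t0, t4, ...``).
    total_cells : sequence of float, scalar, or None
        Bottleneck population sizes ``N_k``.  Alternative to
        ``cells_per_lineage``; one of the two is required for ``"joint"``.
    cells_per_lineage : float or None
        Average bottleneck cells per lineage ``n_bar``; expands to
        ``N_k = n_bar * L``.
    n_dna : float
        Average genomic DNA copies per lineage (enters the default ``beta``).
    c : float or sequence
        Growth/transfer noise per interval; default 1 (offspring variance 2).
    beta : float, sequence, or None
        Read-noise scale per time point; computed from the design when None.
    kappa : float
        Legacy-mode noise scale.
    s_bounds : tuple
        Fitness search box, default ``(-1, 1)``.
    n0_bound_factor : float
        Multiplicative half-width of the ``n0`` box around the plug-in value.
    de_* : differential-evolution hyperparameters (joint mode).
    polish : bool
        L-BFGS-B refinement of the differential-evolution optimum.
    global_search_iters : int
        Outer iterations that re-run the full global search; later iterations
        refine the previous optimum locally (the optimum moves continuously
        with the mean-fitness curve).
    max_iter : int
        Maximum outer iterations.
    rel_tol : float
        Relative-improvement convergence threshold on the summed objective,
        in addition to the strict non-increase rule.
    random_state : int
        Master seed; per-lineage seeds are derived from it and the lineage id,
        so results are independent of lineage order and parallel schedule.
    n_jobs : int
        Parallel degree for the per-lineage optimizations.

    Attributes
    ----------
    fitness_ : ndarray of shape (L,)
        Estimated Malthusian fitness per generation for each lineage.
    n0_ : ndarray of shape (L,)
        Estimated initial bottleneck cell numbers (nan in legacy mode).
    objective_ : ndarray of shape (L,)
        Final per-lineage negative log-likelihood (up to an additive
        constant in joint mode, whose kernels drop normalizing prefactors).
    mean_fitness_ : MeanFitnessCurve
        Final population mean-fitness curve.
    reads_hat_ : ndarray of shape (L, K+1)
        Reconstructed read trajectories.
    n_iter_, objective_history_, converged_, flags_, n_path_, result_
    """

    def __init__(
        self,
        method: str = "joint",
        time_points=None,
        total_cells=None,
        cells_per_lineage=None,
        n_dna: float = 500.0,
        c=1.0,
        beta=None,
        kappa: float = 2.5,
        s_bounds=(-1.0, 1.0),
        n0_bound_factor: float = 50.0,
        de_strategy: str = "best1bin",
        de_popsize: int = 15,
        de_maxiter: int = 120,
        de_tol: float = 1e-3,
        de_mutation=(0.5, 1.0),
        de_recombination: float = 0.7,
        polish: bool = True,
        global_search_iters: int = 1,
        max_iter: int = 15,
        rel_tol: float = 1e-4,
        random_state: int = 0,
        n_jobs: int = 1,
    ):
        self.method = method
        self.time_points = time_points
        self.total_cells = total_cells
        self.cells_per_lineage = cells_per_lineage
        self.n_dna = n_dna
        self.c = c
        self.beta = beta
        self.kappa = kappa
        self.s_bounds = s_bounds
        self.n0_bound_factor = n0_bound_factor
        self.de_strategy = de_strategy
        self.de_popsize = de_popsize
        self.de_maxiter = de_maxiter
        self.de_tol = de_tol
        self.de_mutation = de_mutation
        self.de_recombination = de_recombination
        self.polish = polish
        self.global_search_iters = global_search_iters
        self.max_iter = max_iter
        self.rel_tol = rel_tol
        self.random_state = random_state
        self.n_jobs = n_jobs

    # -- input plumbing ----------------------------------------------------

    def _coerce_input(self, X) -> tuple[ReadMatrix, TimeGrid]:
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            ids = X.index.to_numpy()
            counts = X.to_numpy()
            if self.time_points is not None:
                t = np.asarray(self.time_points, dtype=float)
            else:
                t = np.array([_parse_time_label(c) for c in X.columns], dtype=float)
        else:
            counts = np.asarray(X)
            ids = None
            if self.time_points is None:
                raise ValueError(
                    "time_points is required when X does not carry time labels"
                )
            t = np.asarray(self.time_points, dtype=float)
        grid = TimeGrid(t)
        reads = ReadMatrix(counts=counts, ids=ids)
        if reads.n_timepoints != grid.t.size:
            raise ValueError(
                f"read matrix has {reads.n_timepoints} time columns but "
                f"{grid.t.size} time points were given"
            )
        if reads.n_timepoints < 2:
            raise ValueError("at least two sequencing time points are required")
        if reads.n_lineages == 0:
            raise ValueError("empty read matrix")
        return reads, grid

    def _build_census(self, reads: ReadMatrix, grid: TimeGrid) -> CellCensus | None:
        if self.total_cells is not None:
            N = np.broadcast_to(
                np.atleast_1d(np.asarray(self.total_cells, dtype=float)),
                (grid.t.size,),
            )
            return CellCensus.from_total_cells(N, reads.n_lineages)
        if self.cells_per_lineage is not None:
            return CellCensus.from_cells_per_lineage(
                self.cells_per_lineage, reads.n_lineages, grid.t.size
            )
        if self.method == "joint":
            raise ValueError(
                "joint mode requires total_cells or cells_per_lineage "
                "(the bottleneck census is part of the experimental design)"
            )
        return None

    def _build_noise(
        self, reads: ReadMatrix, grid: TimeGrid, census: CellCensus | None
    ) -> NoiseParameters:
        if census is None:  # legacy mode: only kappa is used
            return NoiseParameters(
                c=np.ones(grid.K), beta=np.ones(grid.t.size), kappa=self.kappa,
                n_dna=self.n_dna,
            )
        return NoiseParameters.with_defaults(
            grid,
            census,
            reads.totals,
            reads.n_lineages,
            c=self.c,
            beta=self.beta,
            kappa=self.kappa,
            n_dna=self.n_dna,
        )

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        """Run the iterative estimation on a count matrix ``X`` (L x K+1)."""
        reads, grid = self._coerce_input(X)
        census = self._build_census(reads, grid)
        noise = self._build_noise(reads, grid, census)
        if self.method == "joint":
            result = self._fit_joint(reads, grid, census, noise)
        elif self.method == "legacy":
            result = self._fit_legacy(reads, grid, noise)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.result_ = result
        self.fitness_ = result.s_hat
        self.n0_ = result.n0_hat
        self.objective_ = result.objective
        self.flags_ = result.flags
        self.n_path_ = result.n_path
        self.reads_hat_ = result.reads_hat
        self.mean_fitness_ = result.mean_fitness
        self.n_iter_ = result.iterations
        self.objective_history_ = result.total_objective
        self.converged_ = result.converged
        self._grid = grid
        self._census = census
        self._noise = noise
        self._totals = reads.totals
        return self

    def _de_opts(self) -> dict:
        return {
            "strategy": self.de_strategy,
            "popsize": self.de_popsize,
            "maxiter": self.de_maxiter,
            "tol": self.de_tol,
            "mutation": self.de_mutation,
            "recombination": self.de_recombination,
            "polish": self.polish,
        }

    def _chunks(self, L: int) -> list[np.ndarray]:
        n_jobs = self.n_jobs if self.n_jobs and self.n_jobs > 0 else 1
        n_chunks = min(max(n_jobs, 1), L)
        return [c for c in np.array_split(np.arange(L), n_chunks) if c.size]

    def _fit_joint(self, reads, grid, census, noise) -> FitResult:
        counts = reads.counts
        totals = reads.totals
        freqs = reads.freqs
        L = reads.n_lineages
        ctx = LikelihoodContext(grid=grid, census=census, noise=noise, totals=totals)
        sbar = init_mean_fitness_v2(grid)
        de_opts = self._de_opts()
        s_bounds = tuple(self.s_bounds)
        chunks = self._chunks(L)
        parallel = Parallel(n_jobs=max(self.n_jobs, 1), prefer="processes")

        best = None
        best_total = np.inf
        history: list[float] = []
        converged = False
        iterations = 0
        for it in range(1, self.max_iter + 1):
            iterations = it
            ctx.set_mean_fitness(sbar)
            if it <= self.global_search_iters:
                if len(chunks) == 1:
                    results = _joint_de_chunk(
                        ctx, counts, totals, chunks[0], reads.ids, s_bounds,
                        self.n0_bound_factor, self.random_state, de_opts,
                    )
                else:
                    parts = parallel(
                        delayed(_joint_de_chunk)(
                            ctx, counts, totals, idx, reads.ids, s_bounds,
                            self.n0_bound_factor, self.random_state, de_opts,
                        )
                        for idx in chunks
                    )
                    results = [r for part in parts for r in part]
            else:
                x0s = [(best[0][i], best[1][i]) for i in range(L)]
                if len(chunks) == 1:
                    results = _joint_refine_chunk(ctx, counts, chunks[0], s_bounds, x0s)
                else:
                    parts = parallel(
                        delayed(_joint_refine_chunk)(
                            ctx, counts, idx, s_bounds, [x0s[i] for i in idx]
                        )
                        for idx in chunks
                    )
                    results = [r for part in parts for r in part]
            s_arr = np.array([r[0] for r in results])
            n0_arr = np.array([r[1] for r in results])
            obj_arr = np.array([r[2] for r in results])
            flag_arr = np.array([r[3] for r in results])
            s_arr, sbar_gauged = _fix_gauge(s_arr, sbar, freqs, grid)
            total = float(np.sum(obj_arr))
            history.append(total)
            if total >= best_total:
                converged = True  # strict non-increase rule: keep previous state
                break
            improvement = (best_total - total) / max(abs(best_total), 1.0)
            best = (s_arr, n0_arr, obj_arr, flag_arr)
            best_sbar_used = sbar_gauged
            best_total = total
            if np.isfinite(improvement) and improvement < self.rel_tol:
                converged = True
                break
            sbar = _weighted_mean_fitness(s_arr, freqs, grid)

        s_arr, n0_arr, obj_arr, flag_arr = best
        estimates = [
            _finalize_joint(
                reads.ids[i], float(s_arr[i]), float(n0_arr[i]), float(obj_arr[i]),
                bool(flag_arr[i]), counts[i].astype(float), totals, census,
                best_sbar_used, noise, grid,
            )
            for i in range(L)
        ]
        final_sbar = _weighted_mean_fitness(s_arr, freqs, grid)
        return FitResult(
            ids=reads.ids,
            s_hat=s_arr,
            n0_hat=n0_arr,
            objective=obj_arr,
            n_path=np.vstack([e.n_path for e in estimates]),
            reads_hat=np.vstack([e.r_hat for e in estimates]),
            flags=[e.flags for e in estimates],
            mean_fitness=final_sbar,
            iterations=iterations,
            total_objective=history,
            method="joint",
            converged=converged,
            seed=self.random_state,
            sbar_fit=best_sbar_used,
        )

    def _fit_legacy(self, reads, grid, noise) -> FitResult:
        counts = reads.counts
        totals = reads.totals
        freqs = reads.freqs
        L = reads.n_lineages
        sbar = init_mean_fitness_v1(reads, grid)
        s_bounds = tuple(self.s_bounds)
        chunks = self._chunks(L)
        parallel = Parallel(n_jobs=max(self.n_jobs, 1), prefer="processes")

        best = None
        best_total = np.inf
        best_sbar_used = sbar
        history: list[float] = []
        converged = False
        iterations = 0
        for it in range(1, self.max_iter + 1):
            iterations = it
            if len(chunks) == 1:
                results = _legacy_chunk(
                    counts, totals, chunks[0], sbar, noise, grid, s_bounds
                )
            else:
                parts = parallel(
                    delayed(_legacy_chunk)(
                        counts, totals, idx, sbar, noise, grid, s_bounds
                    )
                    for idx in chunks
                )
                results = [r for part in parts for r in part]
            s_arr = np.array([r[0] for r in results])
            obj_arr = np.array([r[1] for r in results])
            excl_arr = np.array([r[2] for r in results])
            s_arr, sbar_gauged = _fix_gauge(s_arr, sbar, freqs, grid)
            total = float(np.nansum(obj_arr))
            history.append(total)
            if total >= best_total:
                converged = True  # strict non-increase rule: keep previous state
                break
            improvement = (best_total - total) / max(abs(best_total), 1.0)
            best = (s_arr, obj_arr, excl_arr)
            best_sbar_used = sbar_gauged
            best_total = total
            if np.isfinite(improvement) and improvement < self.rel_tol:
                converged = True
                break
            sbar = _weighted_mean_fitness(s_arr, freqs, grid)

        s_arr, obj_arr, excl_arr = best
        reads_hat = np.empty((L, grid.K + 1))
        flags = []
        for i in range(L):
            if excl_arr[i]:
                reads_hat[i] = np.nan
                flags.append(("zero_reads_excluded",))
            else:
                E = growth_factors(float(s_arr[i]), best_sbar_used, grid)
                row = counts[i].astype(float)
                reads_hat[i, 0] = row[0]
                reads_hat[i, 1:] = row[:-1] * E * totals[1:] / totals[:-1]
                flags.append(())
        final_sbar = _weighted_mean_fitness(s_arr, freqs, grid)
        return FitResult(
            ids=reads.ids,
            s_hat=s_arr,
            n0_hat=np.full(L, np.nan),
            objective=obj_arr,
            n_path=np.full((L, grid.K), np.nan),
            reads_hat=reads_hat,
            flags=flags,
            mean_fitness=final_sbar,
            iterations=iterations,
            total_objective=history,
            method="legacy",
            converged=converged,
            seed=self.random_state,
            sbar_fit=best_sbar_used,
        )

    # -- prediction --------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Estimate fitness for lineage rows of ``X`` under the fitted
        mean-fitness curve (frozen; no iterative update)."""
        if not hasattr(self, "mean_fitness_"):
            raise AttributeError("estimator is not fitted yet")
        reads, grid = self._coerce_input(X)
        if grid.t.size != self._grid.t.size or not np.allclose(grid.t, self._grid.t):
            raise ValueError("prediction time points must match the fitted grid")
        # rows are lineages from the fitted sequencing run: score them
        # against the run's totals, census, noise, and mean-fitness curve
        totals = self._totals
        curve = self.result_.sbar_fit or self.mean_fitness_
        if self.method == "legacy":
            out = np.empty(reads.n_lineages)
            for i in range(reads.n_lineages):
                out[i] = _optimize_legacy(
                    reads.counts[i].astype(float), totals, curve,
                    self._noise, grid, tuple(self.s_bounds),
                )[0]
            return out
        census = self._census
        noise = self._noise
        ctx = LikelihoodContext(grid=grid, census=census, noise=noise, totals=totals)
        ctx.set_mean_fitness(curve)
        de_opts = self._de_opts()
        out = np.empty(reads.n_lineages)
        for i in range(reads.n_lineages):
            out[i] = _optimize_joint_de(
                ctx, reads.counts[i].astype(float), totals, tuple(self.s_bounds),
                self.n0_bound_factor, _lineage_seed(self.random_state, reads.ids[i]),
                de_opts,
            )[0]
        return out


def _parse_time_label(label) -> float:
    """Parse a column label like ``t0``/``t4``/``8`` into a time value."""
    s = str(label).strip()
    if s and s[0] in "tT":
        s = s[1:]
    try:
        return float(s)
    except ValueError as exc:
        raise ValueError(f"cannot parse time point from column label {label!r}") from exc


def run_inference(
    counts,
    time_points,
    total_cells=None,
    cells_per_lineage=None,
    method: str = "joint",
    seed: int = 0,
    max_iter: int = 15,
    n_jobs: int = 1,
    **params,
) -> FitResult:
    """Functional wrapper: fit a :class:`FitnessEstimator` and return its
    :class:`FitResult`."""
    est = FitnessEstimator(
        method=method,
        time_points=time_points,
        total_cells=total_cells,
        cells_per_lineage=cells_per_lineage,
        random_state=seed,
        max_iter=max_iter,
        n_jobs=n_jobs,
        **params,
    )
    est.fit(counts)
    return est.result_
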