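"""Unit and property tests for the likelihood core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import barseqfit as bf
from barseqfit.likelihood import (
    LikelihoodContext,
    assemble_path_system,
    solve_path,
)


# ---------------------------------------------------------------------------
# growth factors
# ---------------------------------------------------------------------------


class TestGrowthFactor:
    def test_neutral_lineage_in_neutral_population(self, grid, zero_sbar):
        for k in range(1, grid.K + 1):
            assert bf.growth_factor(0.0, k, zero_sbar, grid) == pytest.approx(1.0)

    def test_lineage_at_mean_fitness_has_flat_frequency(self, grid):
        c = 0.07
        sbar = bf.MeanFitnessCurve(grid, np.full(grid.t.size, c))
        for k in range(1, grid.K + 1):
            assert bf.growth_factor(c, k, sbar, grid) == pytest.approx(1.0)

    def test_direct_evaluation(self, grid, zero_sbar):
        # s=0.1 over a 4-generation interval with zero mean fitness
        assert bf.growth_factor(0.1, 1, zero_sbar, grid) == pytest.approx(
            math.exp(0.4), rel=1e-12
        )

    def test_trapezoid_integral_of_linear_curve(self, grid):
        # piecewise-linear mean fitness: the interval integral is exact
        values = np.array([0.0, 0.1, 0.3, 0.2, 0.2, 0.5])
        sbar = bf.MeanFitnessCurve(grid, values)
        for k in range(1, grid.K + 1):
            expected = 4.0 * (values[k - 1] + values[k]) / 2.0
            assert sbar.interval_integral(k) == pytest.approx(expected)
            assert bf.growth_factor(0.0, k, sbar, grid) == pytest.approx(
                math.exp(-expected)
            )

    @settings(deadline=None, derandomize=True)
    @given(
        s=st.floats(-1, 1),
        delta=st.floats(-0.5, 0.5),
        k=st.integers(1, 5),
    )
    def test_s_dependence_is_exact_exponential(self, s, delta, k):
        grid = bf.TimeGrid(np.array([0.0, 4.0, 8.0, 12.0, 16.0, 20.0]))
        sbar = bf.MeanFitnessCurve(grid, np.linspace(0, 0.3, 6))
        dt = grid.t[k] - grid.t[k - 1]
        lhs = bf.growth_factor(s + delta, k, sbar, grid)
        rhs = bf.growth_factor(s, k, sbar, grid) * math.exp(delta * dt)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_rejects_nonfinite_fitness(self, grid, zero_sbar):
        with pytest.raises(ValueError):
            bf.growth_factor(math.nan, 1, zero_sbar, grid)


# ---------------------------------------------------------------------------
# tridiagonal path system
# ---------------------------------------------------------------------------


class TestPathSystem:
    def test_k1_by_hand(self):
        m, b = assemble_path_system([1.0], 1.0, 1.0, 1.0, [10.0], nu0=3.0)
        assert m.shape == (1, 1)
        assert m[0, 0] == pytest.approx(2.0)  # 1/c + rho^2/beta
        assert b[0] == pytest.approx(13.0)  # rho*gamma/beta + sqrt(E)*nu0/c

    def test_k2_by_hand(self):
        m, b = assemble_path_system(
            [1.0, 1.0], 1.0, 1.0, 1.0, [0.0, 0.0], nu0=0.0
        )
        assert np.allclose(m, [[3.0, -1.0], [-1.0, 2.0]])
        assert np.allclose(b, [0.0, 0.0])

    def test_off_tridiagonal_entries_vanish(self):
        rng = np.random.default_rng(0)
        K = 8
        m, _ = assemble_path_system(
            rng.uniform(0.5, 2, K),
            rng.uniform(0.5, 2, K),
            rng.uniform(0.5, 2, K),
            rng.uniform(0.5, 2, K),
            rng.uniform(0, 10, K),
            nu0=1.0,
        )
        mask = np.abs(np.subtract.outer(np.arange(K), np.arange(K))) > 1
        assert np.all(m[mask] == 0.0)

    def test_rejects_empty_system(self):
        with pytest.raises(ValueError):
            assemble_path_system([], 1.0, 1.0, 1.0, [], nu0=1.0)

    def test_k1_closed_form_solution(self):
        # nu1 = (rho*gamma/beta + sqrt(E)*nu0/c) / (1/c + rho^2/beta)
        m, b = assemble_path_system([1.0], 1.0, 1.0, 1.0, [10.0], nu0=10.0)
        sol = solve_path(m, b)
        assert sol.nu[0] == pytest.approx(10.0)
        assert sol.n[0] == pytest.approx(100.0)

    def test_homogeneous_system_gives_zero_path(self):
        m, b = assemble_path_system(
            [1.2, 0.8, 1.0], 1.0, 1.0, 1.0, [0.0, 0.0, 0.0], nu0=0.0
        )
        assert np.allclose(solve_path(m, b).nu, 0.0)

    @pytest.mark.parametrize("trial", range(20))
    def test_thomas_matches_dense_solve(self, trial):
        rng = np.random.default_rng(100 + trial)
        K = int(rng.integers(1, 51))
        m, b = assemble_path_system(
            rng.uniform(0.3, 3, K),
            rng.uniform(0.3, 3, K),
            rng.uniform(0.3, 3, K),
            rng.uniform(0.3, 3, K),
            rng.uniform(0, 20, K),
            nu0=rng.uniform(0, 15),
        )
        nu = solve_path(m, b).nu
        dense = np.linalg.solve(m, b)
        if np.any(dense < 0):  # solve_path clamps; compare pre-clamp values
            return
        rel = np.max(np.abs(nu - dense) / np.maximum(np.abs(dense), 1e-30))
        assert rel <= 1e-10


# ---------------------------------------------------------------------------
# joint likelihood
# ---------------------------------------------------------------------------


def _brute_force_nll_k2(s, n0, reads, totals, N, c, beta, sbar, grid):
    """Independent oracle: minimize the K=2 path exponent on a zooming grid,
    then add the t0 read term."""
    E = np.exp(grid.dt * s - sbar.interval_integrals())
    rho = np.sqrt(totals / N)
    gamma = np.sqrt(reads)

    def objective(n1, n2):
        nu = [math.sqrt(n0), math.sqrt(n1), math.sqrt(n2)]
        tot = 0.0
        for k in (1, 2):
            tot += (nu[k] - math.sqrt(E[k - 1]) * nu[k - 1]) ** 2 / c
            tot += (rho[k] * nu[k] - gamma[k]) ** 2 / beta
        return tot

    implied = reads * N / totals  # cell numbers implied by the reads alone
    hi = [
        4.0 * max(n0 * E[0], implied[1], c),
        4.0 * max(n0 * E[0] * E[1], implied[2], c),
    ]
    center = [h / 2 for h in hi]
    width = [h / 2 for h in hi]
    best = (math.inf, center)
    for _ in range(30):
        g1 = np.linspace(max(center[0] - width[0], 0), center[0] + width[0], 41)
        g2 = np.linspace(max(center[1] - width[1], 0), center[1] + width[1], 41)
        for a in g1:
            for bb in g2:
                v = objective(a, bb)
                if v < best[0]:
                    best = (v, [a, bb])
        center = best[1]
        width = [w * 0.12 for w in width]
    return best[0] + (gamma[0] - rho[0] * math.sqrt(n0)) ** 2 / beta


class TestJointLikelihood:
    def test_zero_on_noiseless_trajectory(self, small_pool, grid):
        p = small_pool
        census = bf.CellCensus.from_total_cells(p["N"], p["s_true"].size)
        sbar = bf.MeanFitnessCurve(grid, p["sbar_values"])
        noise = bf.NoiseParameters.with_defaults(
            grid, census, p["totals"], p["s_true"].size
        )
        for i in range(p["s_true"].size):
            val = bf.neg_log_likelihood_v2(
                p["s_true"][i], p["n0_true"][i], p["reads"][i],
                p["totals"], census, sbar, noise, grid,
            )
            assert val == pytest.approx(0.0, abs=1e-18)

    def test_positive_on_any_perturbation(self, small_pool, grid):
        p = small_pool
        census = bf.CellCensus.from_total_cells(p["N"], p["s_true"].size)
        sbar = bf.MeanFitnessCurve(grid, p["sbar_values"])
        noise = bf.NoiseParameters.with_defaults(
            grid, census, p["totals"], p["s_true"].size
        )
        for k in range(grid.K + 1):
            reads = p["reads"][0].copy()
            reads[k] += 5.0
            val = bf.neg_log_likelihood_v2(
                p["s_true"][0], p["n0_true"][0], reads,
                p["totals"], census, sbar, noise, grid,
            )
            assert val > 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_grid_on_k2(self, seed):
        rng = np.random.default_rng(seed)
        grid = bf.TimeGrid(np.array([0.0, 4.0, 8.0]))
        L, n_bar = 100, 100.0
        N = np.full(3, n_bar * L)
        totals = np.full(3, 50.0 * L)
        census = bf.CellCensus.from_total_cells(N, L)
        c_val, beta_val = 1.0, 0.85
        noise = bf.NoiseParameters(c=np.full(2, c_val), beta=np.full(3, beta_val))
        sbar = bf.MeanFitnessCurve(grid, rng.normal(0, 0.05, 3))
        reads = rng.uniform(10, 200, 3)
        s = rng.uniform(-0.3, 0.3)
        n0 = rng.uniform(50, 200)

        fast = bf.neg_log_likelihood_v2(
            s, n0, reads, totals, census, sbar, noise, grid
        )
        brute = _brute_force_nll_k2(
            s, n0, reads, totals, N, c_val, beta_val, sbar, grid
        )
        assert fast == pytest.approx(brute, abs=1e-6)

    def test_batch_agrees_with_scalar(self, grid):
        rng = np.random.default_rng(7)
        L = 50
        census = bf.CellCensus.from_cells_per_lineage(100.0, L, grid.t.size)
        totals = np.full(grid.t.size, 50.0 * L)
        noise = bf.NoiseParameters.with_defaults(grid, census, totals, L)
        sbar = bf.MeanFitnessCurve(grid, rng.normal(0, 0.05, grid.t.size))
        reads = rng.integers(0, 300, grid.t.size).astype(float)
        ctx = LikelihoodContext(grid=grid, census=census, noise=noise, totals=totals)
        ctx.set_mean_fitness(sbar)
        s_arr = rng.uniform(-1, 1, 30)
        n0_arr = rng.uniform(1, 300, 30)
        batch = ctx.nll_batch(np.sqrt(reads), s_arr, n0_arr)
        for j in range(30):
            scalar = bf.neg_log_likelihood_v2(
                s_arr[j], n0_arr[j], reads, totals, census, sbar, noise, grid
            )
            assert batch[j] == pytest.approx(scalar, rel=1e-12, abs=1e-12)

    def test_zero_reads_are_legal(self, grid, zero_sbar):
        L = 10
        census = bf.CellCensus.from_cells_per_lineage(100.0, L, grid.t.size)
        totals = np.full(grid.t.size, 500.0)
        noise = bf.NoiseParameters.with_defaults(grid, census, totals, L)
        reads = np.array([50.0, 20.0, 5.0, 0.0, 0.0, 0.0])
        val = bf.neg_log_likelihood_v2(
            -0.5, 100.0, reads, totals, census, zero_sbar, noise, grid
        )
        assert np.isfinite(val) and val >= 0

    def test_rejects_nonpositive_n0(self, grid, zero_sbar):
        L = 10
        census = bf.CellCensus.from_cells_per_lineage(100.0, L, grid.t.size)
        totals = np.full(grid.t.size, 500.0)
        noise = bf.NoiseParameters.with_defaults(grid, census, totals, L)
        reads = np.full(grid.t.size, 50.0)
        with pytest.raises(ValueError):
            bf.neg_log_likelihood_v2(
                0.0, 0.0, reads, totals, census, zero_sbar, noise, grid
            )


# ---------------------------------------------------------------------------
# legacy likelihood
# ---------------------------------------------------------------------------


class TestLegacyLikelihood:
    def _noise(self, kappa=2.5):
        return bf.NoiseParameters(c=np.ones(1), beta=np.ones(2), kappa=kappa)

    def test_k1_toy_matches_hand_evaluation(self):
        # r0=r1=100, equal totals, s=0, sbar=0, kappa=2.5: zero residual,
        # value = -log prefactor = -0.5*log(sqrt(100)/(4*pi*2.5*100^1.5))
        grid = bf.TimeGrid(np.array([0.0, 4.0]))
        sbar = bf.MeanFitnessCurve.zero(grid)
        val = bf.neg_log_likelihood_v1(
            0.0, np.array([100.0, 100.0]), np.array([1000.0, 1000.0]),
            sbar, self._noise(), grid,
        )
        prefactor = math.sqrt(math.sqrt(100.0) / (4 * math.pi * 2.5 * 100.0**1.5))
        assert val == pytest.approx(-math.log(prefactor), rel=1e-12)

    def test_zero_residual_leaves_only_prefactor(self):
        grid = bf.TimeGrid(np.array([0.0, 4.0]))
        sbar = bf.MeanFitnessCurve.zero(grid)
        # reads follow the deterministic map r1 = r0 * E * R1/R0 with E=1
        val = bf.neg_log_likelihood_v1(
            0.0, np.array([80.0, 40.0]), np.array([1000.0, 500.0]),
            sbar, self._noise(), grid,
        )
        mu = 80.0 * 1.0 * 500.0 / 1000.0
        prefactor = math.sqrt(math.sqrt(mu) / (4 * math.pi * 2.5 * 40.0**1.5))
        assert val == pytest.approx(-math.log(prefactor), rel=1e-12)

    def test_exponent_shrinks_as_kappa_grows(self):
        grid = bf.TimeGrid(np.array([0.0, 4.0]))
        sbar = bf.MeanFitnessCurve.zero(grid)
        reads = np.array([100.0, 150.0])
        totals = np.array([1000.0, 1000.0])

        def exponent(kappa):
            val = bf.neg_log_likelihood_v1(
                0.0, reads, totals, sbar, self._noise(kappa), grid
            )
            mu = 100.0
            prefactor = math.sqrt(
                math.sqrt(mu) / (4 * math.pi * kappa * 150.0**1.5)
            )
            return val + math.log(prefactor)

        exps = [exponent(k) for k in (1.0, 2.5, 5.0, 10.0)]
        assert all(a > b for a, b in zip(exps, exps[1:]))

    def test_zero_read_returns_sentinel(self, grid, zero_sbar):
        noise = bf.NoiseParameters(c=np.ones(grid.K), beta=np.ones(grid.t.size))
        reads = np.array([100.0, 50.0, 0.0, 10.0, 5.0, 2.0])
        totals = np.full(grid.t.size, 1000.0)
        assert math.isnan(
            bf.neg_log_likelihood_v1(0.0, reads, totals, zero_sbar, noise, grid)
        )


# ---------------------------------------------------------------------------
# default beta
# ---------------------------------------------------------------------------


class TestDefaultBeta:
    def test_reference_design_value(self):
        assert bf.default_beta(50.0, 100.0, 500.0) == pytest.approx(0.85)

    def test_direct_evaluation(self):
        assert bf.default_beta(100.0, 100.0, 500.0) == pytest.approx(1.2)

    def test_low_depth_limit_is_half(self):
        # only the sequencing layer survives as r_bar -> 0
        assert bf.default_beta(1e-12, 100.0, 500.0) == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True)
    @given(
        r=st.floats(1, 500),
        n=st.floats(10, 1e4),
        d=st.floats(10, 1e4),
        bump=st.floats(0.1, 100),
    )
    def test_monotonicity(self, r, n, d, bump):
        base = bf.default_beta(r, n, d)
        assert bf.default_beta(r + bump, n, d) > base
        assert bf.default_beta(r, n + bump, d) < base
        assert bf.default_beta(r, n, d + bump) < base

    def test_rejects_nonpositive_arguments(self):
        for args in [(0, 100, 500), (50, -1, 500), (50, 100, 0)]:
            with pytest.raises(ValueError):
                bf.default_beta(*args)
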