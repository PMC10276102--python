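import numpy as np
import pytest

import barseqfit as bf


@pytest.fixture
def grid():
    """Standard 20-generation assay sequenced every 4 generations."""
    return bf.TimeGrid(np.array([0.0, 4.0, 8.0, 12.0, 16.0, 20.0]))


@pytest.fixture
def zero_sbar(grid):
    return bf.MeanFitnessCurve.zero(grid)


@pytest.fixture
def small_pool(grid):
    """Deterministic (noise-free) 12-lineage pool with known parameters.

    Fitnesses are centered under the initial-frequency weights so the truth
    sits in the same gauge the estimator reports (mean fitness zero at t0).
    """
    rng = np.random.default_rng(42)
    L = 12
    s_true = rng.normal(0.0, 0.15, L)
    n0_true = rng.gamma(20.0, 5.0, L)
    s_true = s_true - np.average(s_true, weights=n0_true)
    reads, totals, N, sbar_values = bf.deterministic_reads(
        s_true, n0_true, grid.t, reads_per_lineage=100.0
    )
    return {
        "s_true": s_true,
        "n0_true": n0_true,
        "reads": reads,
        "totals": totals,
        "N": N,
        "sbar_values": sbar_values,
        "grid": grid,
    }
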