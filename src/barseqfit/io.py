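"""CSV/JSON plumbing for count tables, fit results, and simulations.

All tables are plain comma-separated UTF-8 with '.' decimals.  Count tables
carry their sequencing time points in the header (``lineage,t0,t4,...``) so
the time grid cannot drift apart from the matrix.  Every output directory
includes a JSON metadata file with the configuration and seed needed to
regenerate it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inference import FitResult, _parse_time_label
from .likelihood import MeanFitnessCurve, TimeGrid
from .simulate import SimulationTruth

__all__ = [
    "read_count_table",
    "write_count_table",
    "write_fit_result",
    "read_fit_result",
    "write_simulation",
]


def read_count_table(path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a lineage x time-point count CSV.

    The first column holds lineage identifiers; remaining column labels are
    time points in generations (``t0``/``t4`` or bare numbers).  Returns the
    counts as a DataFrame indexed by lineage id plus the parsed time-point
    array.  Negative, missing, or non-integer cells are rejected with the
    offending location.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] < 2:
        raise ValueError("count table needs at least two time-point columns")
    time_points = np.array([_parse_time_label(c) for c in df.columns], dtype=float)
    for col in df.columns:
        vals = df[col]
        if vals.isna().any():
            row = vals.index[vals.isna()][0]
            raise ValueError(f"missing count at lineage {row!r}, column {col!r}")
        as_float = vals.astype(float)
        if (as_float < 0).any():
            row = vals.index[as_float < 0][0]
            raise ValueError(f"negative count at lineage {row!r}, column {col!r}")
        if not np.allclose(as_float, np.rint(as_float)):
            row = vals.index[~np.isclose(as_float, np.rint(as_float))][0]
            raise ValueError(f"non-integer count at lineage {row!r}, column {col!r}")
    counts = df.astype(np.int64)
    TimeGrid(time_points)  # validates ordering
    return counts, time_points


def write_count_table(path, counts, time_points, ids=None) -> None:
    """Write a count matrix with time points encoded in the header."""
    counts = np.asarray(counts)
    time_points = np.asarray(time_points, dtype=float)
    if ids is None:
        ids = np.arange(counts.shape[0])
    cols = [f"t{t:g}" for t in time_points]
    df = pd.DataFrame(counts, index=pd.Index(ids, name="lineage"), columns=cols)
    df.to_csv(path)


def write_fit_result(result: FitResult, outdir, config_echo: dict | None = None) -> dict:
    """Write a fit as three files under ``outdir``.

    ``estimates.csv`` — per-lineage id, s_hat, n0_hat, objective, flags, and
    reconstructed reads; ``mean_fitness.csv`` — the final curve at each
    sequenced time point; ``metadata.json`` — config echo, seed, iteration
    count, objective history, and software version.  In joint mode the
    objective is a negative log-likelihood up to an additive constant (the
    kernels drop their normalizing prefactors), which the metadata records.
    Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    est_path = outdir / "estimates.csv"
    result.to_frame().to_csv(est_path, index=False)

    mf_path = outdir / "mean_fitness.csv"
    pd.DataFrame(
        {"t": result.mean_fitness.grid.t, "s_bar": result.mean_fitness.values}
    ).to_csv(mf_path, index=False)

    meta = {
        "version": __version__,
        "method": result.method,
        "seed": result.seed,
        "iterations": result.iterations,
        "objective_history": list(map(float, result.total_objective)),
        "converged": result.converged,
        "n_lineages": int(result.ids.size),
        "objective_note": (
            "negative log-likelihood up to an additive constant "
            "(exponent-only kernels)" if result.method == "joint"
            else "negative log-likelihood (full density)"
        ),
        "config": config_echo or {},
    }
    meta_path = outdir / "metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    return {"estimates": est_path, "mean_fitness": mf_path, "metadata": meta_path}


def read_fit_result(outdir) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Read back the three files written by :func:`write_fit_result`."""
    outdir = Path(outdir)
    est = pd.read_csv(outdir / "estimates.csv")
    mf = pd.read_csv(outdir / "mean_fitness.csv")
    meta = json.loads((outdir / "metadata.json").read_text())
    return est, mf, meta


def write_simulation(truth: SimulationTruth, outdir) -> dict:
    """Write a simulated experiment: reads, truth table, and config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads_path = outdir / "reads.csv"
    write_count_table(reads_path, truth.read_matrix, truth.time_points)
    truth_path = outdir / "truth.csv"
    pd.DataFrame(
        {
            "lineage": np.arange(truth.s_true.size),
            "s_true": truth.s_true,
            "n0_true": truth.n0_true,
        }
    ).to_csv(truth_path, index=False)
    config_path = outdir / "config.json"
    config_path.write_text(json.dumps(truth.config.to_dict(), indent=2))
    return {"reads": reads_path, "truth": truth_path, "config": config_path}
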