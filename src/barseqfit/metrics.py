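"""Accuracy metrics for parameter recovery on simulated experiments.

Inference quality is scored against simulation truth by the Pearson
correlation between true and inferred values, the mean absolute error
``eps_abs = mean |x* - x_hat|``, and the fraction of lineages for which one
method's fitness error is strictly smaller than another's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "MetricsReport",
    "pearson",
    "mean_abs_error",
    "fraction_improved",
    "evaluate",
]


def pearson(x, y) -> float:
    """Pearson product-moment correlation; rejects constant inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def mean_abs_error(truth, estimate) -> float:
    """Mean absolute error over lineages, ``mean |truth - estimate|``."""
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if truth.shape != estimate.shape:
        raise ValueError("truth and estimate must have equal length")
    return float(np.mean(np.abs(truth - estimate)))


def fraction_improved(err_a, err_b) -> float:
    """Fraction of lineages where ``|err_a| < |err_b|`` (ties not improved)."""
    err_a = np.asarray(err_a, dtype=float)
    err_b = np.asarray(err_b, dtype=float)
    if err_a.shape != err_b.shape:
        raise ValueError("error vectors must have equal length")
    return float(np.mean(np.abs(err_a) < np.abs(err_b)))


@dataclass
class MetricsReport:
    """Recovery metrics for one (method, scenario) combination."""

    method: str
    pearson_s: float
    mae_s: float
    pearson_n0: float | None = None
    mae_n0: float | None = None
    mae_reads_k: float | None = None
    read_timepoint: int | None = None
    frac_improved: float | None = None
    n_lineages: int = 0
    n_scored: int = 0

    def to_json(self, **extra) -> str:
        d = asdict(self)
        d.update(extra)
        return json.dumps(d, indent=2)

    def to_row(self) -> dict:
        return asdict(self)


def evaluate(
    truth,
    result,
    baseline=None,
    read_timepoint: int = 2,
) -> MetricsReport:
    """Score a fit against simulation truth.

    ``truth`` is a :class:`~barseqfit.simulate.SimulationTruth`; ``result``
    (and the optional ``baseline`` for the improved-fraction comparison) are
    :class:`~barseqfit.inference.FitResult` objects on the same lineages.
    Lineages whose estimate is the ``nan`` sentinel (legacy zero-read
    exclusions) are dropped from the scored set; ``n_scored`` records how
    many remain.  Read-trajectory error is reported at ``read_timepoint``
    (column index into the sequenced time points).
    """
    s_true = np.asarray(truth.s_true, dtype=float)
    s_hat = np.asarray(result.s_hat, dtype=float)
    mask = np.isfinite(s_hat)
    report = MetricsReport(
        method=result.method,
        pearson_s=pearson(s_true[mask], s_hat[mask]),
        mae_s=mean_abs_error(s_true[mask], s_hat[mask]),
        n_lineages=s_true.size,
        n_scored=int(mask.sum()),
    )
    n0_hat = np.asarray(result.n0_hat, dtype=float)
    if np.any(np.isfinite(n0_hat)):
        m = mask & np.isfinite(n0_hat)
        report.pearson_n0 = pearson(truth.n0_true[m], n0_hat[m])
        report.mae_n0 = mean_abs_error(truth.n0_true[m], n0_hat[m])
    if result.reads_hat is not None and read_timepoint < truth.read_matrix.shape[1]:
        r_hat_k = result.reads_hat[:, read_timepoint]
        m = mask & np.isfinite(r_hat_k)
        report.mae_reads_k = mean_abs_error(
            truth.read_matrix[m, read_timepoint], r_hat_k[m]
        )
        report.read_timepoint = read_timepoint
    if baseline is not None:
        base_hat = np.asarray(baseline.s_hat, dtype=float)
        m = mask & np.isfinite(base_hat)
        report.frac_improved = fraction_improved(
            s_hat[m] - s_true[m], base_hat[m] - s_true[m]
        )
    return report
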