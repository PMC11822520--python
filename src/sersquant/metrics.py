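"""Replicate-experiment aggregation and method-comparison statistics.

The comparison mirrors how replicate calibration experiments are normally
summarized: slopes and R^2 averaged across experiments; replicate responses
averaged position-wise across experiments (well r of experiment 1..E gives
one pooled value per well position) before computing the per-concentration
relative standard deviation (RSD = sample std / mean) and its reciprocal,
reported as S/N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve

__all__ = [
    "ExperimentAggregate",
    "MethodComparison",
    "aggregate_experiments",
    "rsd_per_concentration",
    "sn_per_concentration",
    "build_comparison",
]


@dataclass
class ExperimentAggregate:
    """Cross-experiment summary of one quantification method."""

    method: str
    concentrations: np.ndarray
    mean_slope: float
    mean_r_squared: float
    pooled_replicate_responses: np.ndarray  # (n_concentrations, n_replicates)


def aggregate_experiments(curves: Sequence[CalibrationCurve]) -> ExperimentAggregate:
    """Average slopes/R^2 and position-wise replicate responses."""
    if len(curves) == 0:
        raise ValueError("at least one experiment is required")
    first = curves[0]
    for c in curves[1:]:
        if c.method != first.method:
            raise ValueError("experiments mix different methods")
        if not np.array_equal(c.concentrations, first.concentrations):
            raise ValueError("experiments use different concentration designs")
        if c.replicate_responses.shape != first.replicate_responses.shape:
            raise ValueError("experiments have different replicate layouts")
    return ExperimentAggregate(
        method=first.method,
        concentrations=first.concentrations.copy(),
        mean_slope=float(np.mean([c.slope for c in curves])),
        mean_r_squared=float(np.mean([c.r_squared for c in curves])),
        pooled_replicate_responses=np.mean(
            [c.replicate_responses for c in curves], axis=0
        ),
    )


def rsd_per_concentration(replicate_responses: np.ndarray) -> np.ndarray:
    """Sample std / mean of each concentration's replicate responses.

    Accepts a (n_concentrations, n_replicates) array or a single 1-D row.
    """
    r = np.asarray(replicate_responses, dtype=float)
    squeeze = r.ndim == 1
    if squeeze:
        r = r[None, :]
    if r.shape[1] < 2:
        raise ValueError("at least two replicates are required")
    means = r.mean(axis=1)
    if np.any(means == 0):
        raise ValueError("RSD undefined: a concentration has zero mean response")
    rsd = r.std(axis=1, ddof=1) / means
    return float(rsd[0]) if squeeze else rsd


def sn_per_concentration(rsd: np.ndarray | float) -> np.ndarray | float:
    """Reciprocal of the RSD; an RSD of exactly 0 reports infinite S/N."""
    r = np.asarray(rsd, dtype=float)
    if np.any(r < 0):
        raise ValueError("RSD must be nonnegative")
    with np.errstate(divide="ignore"):
        sn = np.where(r == 0, np.inf, 1.0 / np.where(r == 0, 1.0, r))
    return float(sn) if np.isscalar(rsd) or np.ndim(rsd) == 0 else sn


@dataclass
class MethodComparison:
    """The three comparison tables plus per-row winner flags.

    ``summary`` has rows ``slope`` / ``r_squared``; ``rsd`` and ``sn`` are
    indexed by concentration (ng/mL) with one column per method.
    """

    summary: pd.DataFrame
    rsd: pd.DataFrame
    sn: pd.DataFrame
    winners: dict[str, pd.Series | str]


def build_comparison(
    curves_by_method: Mapping[str, Sequence[CalibrationCurve]],
    methods: Sequence[str] | None = None,
) -> MethodComparison:
    """Aggregate every method's experiments and tabulate the comparison.

    ``methods`` optionally names the methods that must be present; a named
    method missing from ``curves_by_method`` is an error.
    """
    if methods is not None:
        missing = [m for m in methods if m not in curves_by_method]
        if missing:
            raise ValueError(f"missing methods: {missing}")
        curves_by_method = {m: curves_by_method[m] for m in methods}
    if not curves_by_method:
        raise ValueError("no methods to compare")

    aggregates = {
        name: aggregate_experiments(curves)
        for name, curves in curves_by_method.items()
    }
    concentrations = next(iter(aggregates.values())).concentrations
    for agg in aggregates.values():
        if not np.array_equal(agg.concentrations, concentrations):
            raise ValueError("methods were run on different concentration designs")

    summary = pd.DataFrame(
        {
            name: [agg.mean_slope, agg.mean_r_squared]
            for name, agg in aggregates.items()
        },
        index=["slope", "r_squared"],
    )
    rsd = pd.DataFrame(
        {
            name: rsd_per_concentration(agg.pooled_replicate_responses)
            for name, agg in aggregates.items()
        },
        index=pd.Index(concentrations, name="concentration_ng_mL"),
    )
    sn = rsd.apply(sn_per_concentration)

    winners: dict[str, pd.Series | str] = {
        "slope": summary.loc["slope"].idxmax(),
        "r_squared": summary.loc["r_squared"].idxmax(),
        "rsd": rsd.idxmin(axis=1),
        "sn": sn.idxmax(axis=1),
    }
    return MethodComparison(summary=summary, rsd=rsd, sn=sn, winners=winners)
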