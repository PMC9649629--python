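"""Summary statistics: total production, duration of function, aggregation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .batch import StochasticResult
from .trajectory import Trajectory

__all__ = [
    "SummaryRow",
    "total_production",
    "duration_of_function",
    "summarize",
    "summary_table",
    "NoProductionError",
]


class NoProductionError(ValueError):
    """Duration of function is undefined for an all-zero production series."""


@dataclass(frozen=True)
class SummaryRow:
    """Per-scenario replicate statistics (sample SD, n−1 denominator)."""

    scenario_id: str
    label: str
    total_production_mean: float
    total_production_sd: float
    duration_mean: float
    duration_sd: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if self.total_production_sd < 0 or self.duration_sd < 0:
            raise ValueError("standard deviations must be non-negative")


ResultLike = Union[Trajectory, StochasticResult]


def _trajectory(result: ResultLike) -> Trajectory:
    return result.trajectory if isinstance(result, StochasticResult) else result


def total_production(traj: ResultLike) -> float:
    """Final value of the cumulative production series (arbitrary units)."""
    t = _trajectory(traj)
    if t.time.size == 0:
        raise ValueError("empty trajectory")
    return float(t.cumulative_production[-1])


def duration_of_function(traj: ResultLike, fraction: float = 0.95) -> float:
    """Earliest time at which cumulative production reaches ``fraction`` of
    its final value, linearly interpolated between grid points.

    "Production is 95% of max" is read on the cumulative series, which is
    monotone, so the maximum is the final value and the crossing time is
    well defined.  Raises :class:`NoProductionError` when nothing was
    produced.
    """
    t = _trajectory(traj)
    cum = np.asarray(t.cumulative_production, dtype=float)
    if cum.size == 0:
        raise ValueError("empty trajectory")
    final = cum[-1]
    if final <= 0:
        raise NoProductionError("cumulative production is zero everywhere")
    target = fraction * final
    idx = int(np.searchsorted(cum, target, side="left"))
    if idx == 0:
        return float(t.time[0])
    t0, t1 = t.time[idx - 1], t.time[idx]
    c0, c1 = cum[idx - 1], cum[idx]
    if c1 == c0:
        return float(t1)
    return float(t0 + (target - c0) / (c1 - c0) * (t1 - t0))


def summarize(results: Sequence[ResultLike], label: str = "",
              fraction: float = 0.95) -> SummaryRow:
    """Mean ± sample SD of total production and duration across replicates.

    All results must come from the same scenario; a single replicate is
    summarized with SD = 0 (degenerate, but well defined).
    """
    if len(results) == 0:
        raise ValueError("summarize requires at least one result")
    ids = {(_trajectory(r).meta or {}).get("scenario_id", "") for r in results}
    if len(ids) > 1:
        raise ValueError(f"mixed scenarios in summarize: {sorted(ids)}")
    totals = np.array([total_production(r) for r in results])
    durations = np.array([duration_of_function(r, fraction) for r in results])
    n = len(results)
    sd = (lambda x: float(np.std(x, ddof=1))) if n > 1 else (lambda x: 0.0)
    return SummaryRow(
        scenario_id=next(iter(ids)),
        label=label or (_trajectory(results[0]).meta or {}).get("label", ""),
        total_production_mean=float(totals.mean()),
        total_production_sd=sd(totals),
        duration_mean=float(durations.mean()),
        duration_sd=sd(durations),
        n_replicates=n,
    )


def summary_table(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    """One row per scenario, ready for CSV export."""
    return pd.DataFrame([row.__dict__ for row in rows])
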