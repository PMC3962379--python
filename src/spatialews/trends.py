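"""Trend statistics of indicators along a degradation gradient.

An indicator is evaluated per snapshot along the gradient; the strength of
its monotone trend is quantified with Kendall's tau-b (tie-corrected, the
default — discrete-data indicators tie frequently) or Pearson's r between
stress (or rank) and indicator value.  tau is rank-based, so using ranks
in place of the raw driver values changes nothing for monotone gradients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats

from .grid import GradientSequence, SpatialGrid
from .indicators import UndefinedIndicatorError

__all__ = ["IndicatorTrajectory", "TrendResult", "indicator_trajectory", "trend_statistic"]


@dataclass(frozen=True)
class IndicatorTrajectory:
    """Per-snapshot values of one indicator along a gradient.

    Snapshots where the indicator is undefined (e.g. skewness of a
    constant field) hold NaN and are excluded pairwise from trend
    statistics; ``n_valid`` counts the defined entries.
    """

    indicator: str
    stress: tuple[float, ...]
    values: np.ndarray

    @property
    def n_valid(self) -> int:
        return int(np.sum(~np.isnan(self.values)))

    def __len__(self) -> int:
        return len(self.stress)


@dataclass(frozen=True)
class TrendResult:
    method: Literal["kendall", "pearson"]
    statistic: float
    p_value: float
    n: int


def indicator_trajectory(
    seq: GradientSequence,
    indicator: Callable[[SpatialGrid], float | None] | str,
    name: str | None = None,
) -> IndicatorTrajectory:
    """Apply an indicator independently to every snapshot.

    ``indicator`` is a callable mapping a grid to a scalar (or None/NaN
    where undefined), or the name of a registered scalar statistic from
    :data:`spatialews.nullmodels.STATISTICS`.
    """
    if isinstance(indicator, str):
        from .nullmodels import STATISTICS

        name = name or indicator
        fn = STATISTICS[indicator]
    else:
        fn = indicator
        name = name or getattr(indicator, "__name__", "indicator")
    vals = []
    for g in seq:
        try:
            v = fn(g)
        except UndefinedIndicatorError:
            v = None
        vals.append(np.nan if v is None else float(v))
    return IndicatorTrajectory(
        indicator=name, stress=seq.stress, values=np.array(vals, dtype=float)
    )


def trend_statistic(
    traj: IndicatorTrajectory | Sequence[float],
    method: Literal["kendall", "pearson"] = "kendall",
    stress: Sequence[float] | None = None,
) -> TrendResult:
    """Kendall tau-b or Pearson r of indicator value against stress.

    Undefined (NaN) snapshots are dropped pairwise; at least 3 valid pairs
    are required.  Kendall p-values are exact for small untied samples and
    asymptotic otherwise (scipy's automatic switch).
    """
    if isinstance(traj, IndicatorTrajectory):
        x = np.asarray(traj.stress, float)
        y = traj.values
    else:
        y = np.asarray(traj, float)
        x = np.asarray(stress, float) if stress is not None else np.arange(1.0, y.size + 1)
    ok = ~np.isnan(y) & ~np.isnan(x)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need at least 3 valid points for a trend, got {x.size}")
    if np.all(y == y[0]):
        return TrendResult(method=method, statistic=np.nan, p_value=np.nan, n=x.size)
    if method == "kendall":
        res = stats.kendalltau(x, y, variant="b")
    elif method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown trend method {method!r}")
    return TrendResult(
        method=method,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(x.size),
    )
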