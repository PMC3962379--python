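"""Generic leading indicators computed on a single snapshot.

Spatial variance, spatial skewness and near-neighbour spatial correlation
(Moran's I) are the "generic" early-warning indicators: critical slowing
down near a bifurcation makes fluctuations larger, more asymmetric toward
the alternative state, and more spatially coherent, so all three are
expected to trend as a transition approaches.

Moments use the population (biased) convention, standard in this
literature; trend detection only needs relative change so the n/(n-1)
correction is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .grid import Boundary, SpatialGrid

Weights = Literal["rook", "queen"]

__all__ = [
    "MomentSet",
    "CorrelationResult",
    "spatial_moments",
    "morans_i",
    "correlation_function",
    "UndefinedIndicatorError",
]


class UndefinedIndicatorError(ValueError):
    """Raised when an indicator is undefined on the given grid (e.g. a
    correlation on a constant grid)."""


@dataclass(frozen=True)
class MomentSet:
    """Spatial mean, variance and skewness of a snapshot.

    ``skewness`` is ``None`` (explicitly undefined) when the variance is
    zero: a constant field carries no asymmetry information and reporting 0
    would fabricate symmetry.
    """

    mean: float
    variance: float
    skewness: float | None
    n_cells: int

    @property
    def skewness_defined(self) -> bool:
        return self.skewness is not None


@dataclass(frozen=True)
class CorrelationResult:
    """Moran's I at one lag distance."""

    lag: int
    morans_i: float
    n_pairs: int
    weights_convention: Weights
    boundary: Boundary


def spatial_moments(grid: SpatialGrid | np.ndarray) -> MomentSet:
    """Population mean, variance and skewness over all cells.

    variance = m2 = mean((x - mean)^2); skewness = m3 / m2^(3/2).
    These depend only on the multiset of values, never on their spatial
    arrangement.
    """
    x = grid.values if isinstance(grid, SpatialGrid) else np.asarray(grid, float)
    mean = float(x.mean())
    if np.all(x == x.flat[0]):  # constant field: moments degenerate exactly
        return MomentSet(mean=mean, variance=0.0, skewness=None, n_cells=x.size)
    dev = x - mean
    m2 = float(np.mean(dev**2))
    if m2 == 0.0:  # numerically constant (deviations underflow)
        return MomentSet(mean=mean, variance=0.0, skewness=None, n_cells=x.size)
    m3 = float(np.mean(dev**3))
    s3 = m2**1.5
    if s3 == 0.0:  # variance so small its 3/2 power underflows
        return MomentSet(mean=mean, variance=m2, skewness=None, n_cells=x.size)
    return MomentSet(mean=mean, variance=m2, skewness=m3 / s3, n_cells=x.size)


def _ring_offsets(lag: int, weights: Weights) -> list[tuple[int, int]]:
    """All signed offsets (di, dj) at the given lag distance.

    rook uses the Manhattan ring |di|+|dj| = lag, queen the Chebyshev ring
    max(|di|,|dj|) = lag.  At lag 1 these are the 4- and 8-neighbourhoods.
    """
    offsets = []
    for di in range(-lag, lag + 1):
        for dj in range(-lag, lag + 1):
            if (di, dj) == (0, 0):
                continue
            dist = abs(di) + abs(dj) if weights == "rook" else max(abs(di), abs(dj))
            if dist == lag:
                offsets.append((di, dj))
    return offsets


def morans_i(
    grid: SpatialGrid | np.ndarray,
    lag: int = 1,
    weights: Weights = "rook",
    boundary: Boundary | None = None,
) -> CorrelationResult:
    """Moran's I spatial autocorrelation at a given lag distance.

        I = (N / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

    with w_ij = 1 for cell pairs at the given lag under the chosen
    adjacency and W the number of (ordered) weighted pairs.  Lag-1 rook is
    the headline "spatial correlation at lag one", the spatial analogue of
    lag-1 autocorrelation.

    ``boundary`` defaults to the grid's own topology (periodic for
    simulator output, open for field data).
    """
    if isinstance(grid, SpatialGrid):
        x = grid.values
        if boundary is None:
            boundary = grid.boundary
    else:
        x = np.asarray(grid, float)
        if boundary is None:
            boundary = "open"
    n_half = min(x.shape) // 2
    if lag < 1 or lag > n_half:
        raise ValueError(
            f"lag must be in [1, {n_half}] for a {x.shape[0]}x{x.shape[1]} grid"
        )
    z = x - x.mean()
    denom = float(np.sum(z**2))
    if denom == 0.0:
        raise UndefinedIndicatorError("Moran's I is undefined on a constant grid")

    cross = 0.0
    n_pairs = 0
    for di, dj in _ring_offsets(lag, weights):
        if boundary == "periodic":
            shifted = np.roll(np.roll(z, -di, axis=0), -dj, axis=1)
            cross += float(np.sum(z * shifted))
            n_pairs += z.size
        else:
            a = z[max(0, -di) : z.shape[0] - max(0, di),
                  max(0, -dj) : z.shape[1] - max(0, dj)]
            b = z[max(0, di) : z.shape[0] + min(0, di),
                  max(0, dj) : z.shape[1] + min(0, dj)]
            cross += float(np.sum(a * b))
            n_pairs += a.size
    value = (z.size / n_pairs) * cross / denom
    return CorrelationResult(
        lag=lag,
        morans_i=value,
        n_pairs=n_pairs,
        weights_convention=weights,
        boundary=boundary,
    )


def correlation_function(
    grid: SpatialGrid | np.ndarray,
    max_lag: int,
    weights: Weights = "rook",
    boundary: Boundary | None = None,
) -> list[CorrelationResult]:
    """Moran's I at every integer lag 1..max_lag (no decay assumed)."""
    return [morans_i(grid, lag, weights, boundary) for lag in range(1, max_lag + 1)]
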