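"""Surrogate null models and significance bands.

Indicator values on a single snapshot mean little without a reference: the
null models here generate surrogate grids with the spatial structure
destroyed, and the indicator's distribution over the surrogate ensemble
gives a Monte-Carlo confidence band.

Two surrogates are provided:

* **reshuffle** — a uniformly random permutation of the cell values.  This
  removes all spatial structure while conserving the value multiset, hence
  it conserves spatial variance and skewness *exactly* and cannot serve as
  a null for them; it is the null for spatial correlation, spectra and
  patch-size distributions.
* **gaussian** — iid normal draws with the original grid's sample mean and
  variance (continuous data only).  A valid null for skewness, correlation
  and spectra; rejected as a variance null because the variance is fixed
  by construction.

For variance and skewness the discriminating construction is the
**coarse-graining test**: compare the statistic on the coarse-grained data
with its distribution over coarse-grained reshuffles.  Averaging blocks of
a reshuffled (random) matrix shrinks variability by the block size, while
genuine spatial structure survives coarse-graining — so a structured grid
shows coarse-grained variance above the null band.

For spectra an analytic alternative exists: under a structureless field
the scaled periodogram ordinates are asymptotically proportional to
chi-square(2)/2 variates, so the mean of m ordinates in a ring or sector
follows chi-square(2m)/(2m) times the expected level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats

from .grid import SpatialGrid, coarse_grain
from .indicators import morans_i, spatial_moments
from .spectral import periodogram2d, r_spectrum, theta_spectrum

Method = Literal["reshuffle", "gaussian"]

__all__ = [
    "InvalidNullError",
    "NullBand",
    "BandResult",
    "SurrogateEnsemble",
    "reshuffle_surrogate",
    "gaussian_surrogate",
    "surrogate_ensemble",
    "confidence_band",
    "coarse_grain_null_test",
    "chi2_spectrum_band",
    "spectrum_null_bands",
    "SpectrumBands",
    "STATISTICS",
]


class InvalidNullError(ValueError):
    """Raised when a surrogate method cannot serve as a null for the
    requested statistic (e.g. reshuffling as a variance null)."""


@dataclass(frozen=True)
class NullBand:
    statistic: str
    lower: float | np.ndarray
    upper: float | np.ndarray
    level: float
    n_surrogates: int
    method: str


@dataclass(frozen=True)
class BandResult:
    """A null band together with the observed value and the verdict."""

    band: NullBand
    observed: float | np.ndarray
    significant: bool

    def to_dict(self) -> dict:
        return {
            "statistic": self.band.statistic,
            "observed": _jsonify(self.observed),
            "lower": _jsonify(self.band.lower),
            "upper": _jsonify(self.band.upper),
            "level": self.band.level,
            "n_surrogates": self.band.n_surrogates,
            "method": self.band.method,
            "significant": self.significant,
        }


def _jsonify(x):
    return x.tolist() if isinstance(x, np.ndarray) else x


@dataclass(frozen=True)
class SurrogateEnsemble:
    method: Method
    grids: tuple[SpatialGrid, ...]
    seed_state: str

    @property
    def n(self) -> int:
        return len(self.grids)


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def reshuffle_surrogate(
    grid: SpatialGrid, rng: np.random.Generator | int | None = None
) -> SpatialGrid:
    """Uniformly random permutation of the grid's cell values."""
    rng = _as_rng(rng)
    flat = grid.values.ravel().copy()
    rng.shuffle(flat)
    return grid.with_values(flat.reshape(grid.values.shape))


def gaussian_surrogate(
    grid: SpatialGrid, rng: np.random.Generator | int | None = None
) -> SpatialGrid:
    """iid normal field with the original's sample mean and variance."""
    if grid.value_kind != "continuous":
        raise InvalidNullError(
            "the Gaussian surrogate applies to continuous data only; "
            "discrete occupancy data has no meaningful normal analogue"
        )
    m = spatial_moments(grid)
    if m.variance == 0.0:
        raise InvalidNullError("Gaussian surrogate undefined for a constant grid")
    rng = _as_rng(rng)
    vals = rng.normal(m.mean, np.sqrt(m.variance), size=grid.values.shape)
    return grid.with_values(vals)


def surrogate_ensemble(
    grid: SpatialGrid,
    method: Method = "reshuffle",
    n: int = 200,
    rng: np.random.Generator | int | None = None,
) -> SurrogateEnsemble:
    rng = _as_rng(rng)
    gen = reshuffle_surrogate if method == "reshuffle" else gaussian_surrogate
    grids = tuple(gen(grid, rng) for _ in range(n))
    return SurrogateEnsemble(method=method, grids=grids, seed_state=str(rng.bit_generator.state["state"]))


#: Named scalar indicators usable with :func:`confidence_band`.
STATISTICS: dict[str, Callable[[SpatialGrid], float]] = {
    "variance": lambda g: spatial_moments(g).variance,
    "skewness": lambda g: spatial_moments(g).skewness,
    "mean": lambda g: spatial_moments(g).mean,
    "morans_i": lambda g: morans_i(g, lag=1).morans_i,
}

#: Statistics a given surrogate method is *not* a valid null for.
_INVALID_NULLS = {
    ("reshuffle", "variance"): "reshuffling conserves the value multiset, so "
    "spatial variance is identical on every surrogate",
    ("reshuffle", "skewness"): "reshuffling conserves the value multiset, so "
    "spatial skewness is identical on every surrogate",
    ("gaussian", "variance"): "the Gaussian surrogate fixes the variance to the "
    "original's by construction",
}


def confidence_band(
    grid: SpatialGrid,
    statistic: str | Callable[[SpatialGrid], float],
    method: Method = "reshuffle",
    n: int = 200,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
    strict: bool = True,
) -> BandResult:
    """Monte-Carlo confidence band for a scalar indicator.

    The statistic is evaluated on ``n`` surrogates; the band is the
    empirical ((1-level)/2, (1+level)/2) quantile pair and the observed
    value is flagged significant when it falls outside.

    When the requested (method, statistic) pair is a degenerate null —
    reshuffling for variance/skewness, Gaussian surrogates for variance —
    an :class:`InvalidNullError` is raised unless ``strict=False``, in
    which case the band is computed anyway (it collapses onto the observed
    value for conserved statistics) and never flags significance.
    """
    if isinstance(statistic, str):
        name = statistic
        fn = STATISTICS[statistic]
    else:
        name = getattr(statistic, "__name__", "statistic")
        fn = statistic
    key = (method, name)
    degenerate = key in _INVALID_NULLS
    if degenerate and strict:
        raise InvalidNullError(
            f"{method!r} is not a valid null model for {name!r}: "
            + _INVALID_NULLS[key]
            + "; use the coarse-graining test instead"
        )
    rng = _as_rng(rng)
    gen = reshuffle_surrogate if method == "reshuffle" else gaussian_surrogate
    observed = fn(grid)
    draws = np.array([fn(gen(grid, rng)) for _ in range(n)], dtype=float)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(draws, [alpha, 1.0 - alpha])
    significant = bool(observed < lower or observed > upper) and not degenerate
    band = NullBand(
        statistic=name, lower=float(lower), upper=float(upper),
        level=level, n_surrogates=n, method=method,
    )
    return BandResult(band=band, observed=float(observed), significant=significant)


def coarse_grain_null_test(
    grid: SpatialGrid,
    sub: int,
    statistic: Literal["variance", "skewness"] = "variance",
    n: int = 200,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
    mode: Literal["mean", "count"] = "mean",
) -> BandResult:
    """Coarse-graining null test for spatial variance or skewness.

    Computes the statistic on the block-averaged grid and compares it with
    the same statistic on block-averaged reshuffles.  ``mode='count'``
    (occupancy data) uses occupied-cell counts per block instead of means
    — for the verdict the two are equivalent (counts are means scaled by
    sub^2), but counts put the band on the local-abundance scale.
    ``sub=1`` is allowed but non-discriminating (the coarse-grained matrix
    is the original, so for variance the band collapses onto the observed
    value).
    """
    if statistic not in ("variance", "skewness"):
        raise ValueError("coarse-graining test applies to variance or skewness")
    fn = STATISTICS[statistic]
    rng = _as_rng(rng)
    observed = fn(coarse_grain(grid, sub, mode=mode))
    draws = np.array(
        [
            fn(coarse_grain(reshuffle_surrogate(grid, rng), sub, mode=mode))
            for _ in range(n)
        ],
        dtype=float,
    )
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(draws, [alpha, 1.0 - alpha])
    band = NullBand(
        statistic=f"coarse_{statistic}(sub={sub})",
        lower=float(lower), upper=float(upper),
        level=level, n_surrogates=n, method="coarse_grain+reshuffle",
    )
    significant = bool(observed < lower or observed > upper) and sub > 1
    return BandResult(band=band, observed=float(observed), significant=significant)


def chi2_spectrum_band(
    bin_counts: Sequence[int] | np.ndarray,
    level: float = 0.95,
    mean_power: float = 1.0,
    conjugate_pairs: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic null band for the mean periodogram power per bin.

    For a structureless field each complex periodogram ordinate is
    asymptotically ``mean_power * chi2(2)/2``, so the mean over ``d``
    independent ordinates follows ``mean_power * chi2(2d)/(2d)``.  Bins
    taken over the *full* wavenumber plane (the package default) contain
    every conjugate pair twice — a real field satisfies P(k) = P(-k)
    exactly — so a bin of m ordinates carries only d = m/2 independent
    ones and the band is ``chi2(m)/m``; set ``conjugate_pairs=False`` for
    bins over a half-plane with m distinct ordinates (``chi2(2m)/(2m)``).
    Returns (lower, upper) arrays for the per-ordinate mean power in each
    bin at the given two-sided level.
    """
    m = np.asarray(bin_counts, dtype=int)
    if np.any(m < 1):
        raise ValueError("every bin must contain at least one ordinate")
    df = np.maximum(m, 1) if conjugate_pairs else 2 * m
    alpha = (1.0 - level) / 2.0
    lower = stats.chi2.ppf(alpha, df) / df * mean_power
    upper = stats.chi2.ppf(1.0 - alpha, df) / df * mean_power
    return lower, upper


@dataclass(frozen=True)
class SpectrumBands:
    """Per-ring and per-sector limits for mean spectral power.

    ``radial_upper``/``angular_upper`` are pointwise two-sided limits at
    ``level``; the ``*_fw`` variants control the family-wise error over
    all rings (or sectors) jointly, for decisions of the form "does *any*
    bin exceed its band" (periodicity and anisotropy calls)."""

    radial_lower: np.ndarray
    radial_upper: np.ndarray
    angular_lower: np.ndarray
    angular_upper: np.ndarray
    radial_upper_fw: np.ndarray
    angular_upper_fw: np.ndarray
    level: float
    method: str
    n_surrogates: int


def spectrum_null_bands(
    grid: SpatialGrid,
    n_sectors: int = 12,
    method: Literal["reshuffle", "gaussian", "chi2"] = "reshuffle",
    n: int = 200,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> SpectrumBands:
    """Null bands for the r- and theta-spectrum ring/sector mean power.

    ``method='chi2'`` uses the analytic chi-square ordinate theory with the
    expected flat level estimated from the grid's own total power;
    surrogate methods build empirical quantile bands from ``n`` surrogate
    spectra with identical binning.
    """
    ps = periodogram2d(grid, scale_by_variance=True)
    rs = r_spectrum(ps)
    angs = theta_spectrum(ps, n_sectors=n_sectors)
    if method == "chi2":
        # expected flat per-ordinate level: total power spread over the
        # N-1 non-DC ordinates
        mu_r = float(ps.total_power) / float(ps.power.size - 1)
        rlo, rup = chi2_spectrum_band(rs.counts, level, mu_r)
        alo, aup = chi2_spectrum_band(angs.counts, level, mu_r)
        # Bonferroni-corrected (family-wise) one-sided upper limits
        fw_r = 1.0 - (1.0 - level) / rs.counts.size
        fw_a = 1.0 - (1.0 - level) / angs.counts.size
        rup_fw = chi2_spectrum_band(rs.counts, 2 * fw_r - 1, mu_r)[1]
        aup_fw = chi2_spectrum_band(angs.counts, 2 * fw_a - 1, mu_r)[1]
        return SpectrumBands(rlo, rup, alo, aup, rup_fw, aup_fw, level, "chi2", 0)
    rng = _as_rng(rng)
    gen = reshuffle_surrogate if method == "reshuffle" else gaussian_surrogate
    rdraws = np.empty((n, rs.power.size))
    adraws = np.empty((n, angs.power.size))
    for i in range(n):
        sps = periodogram2d(gen(grid, rng), scale_by_variance=True)
        rdraws[i] = r_spectrum(sps).mean_power
        adraws[i] = theta_spectrum(sps, n_sectors=n_sectors).mean_power
    alpha = (1.0 - level) / 2.0
    # family-wise upper limits from the max-deviation statistic: scale the
    # per-bin surrogate mean by the level-quantile of max_k(draw_k/mean_k)
    rmu = rdraws.mean(axis=0)
    amu = adraws.mean(axis=0)
    rmax = np.quantile((rdraws / rmu).max(axis=1), level)
    amax = np.quantile((adraws / amu).max(axis=1), level)
    return SpectrumBands(
        radial_lower=np.quantile(rdraws, alpha, axis=0),
        radial_upper=np.quantile(rdraws, 1.0 - alpha, axis=0),
        angular_lower=np.quantile(adraws, alpha, axis=0),
        angular_upper=np.quantile(adraws, 1.0 - alpha, axis=0),
        radial_upper_fw=rmax * rmu,
        angular_upper_fw=amax * amu,
        level=level,
        method=method,
        n_surrogates=n,
    )
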