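"""Decision-flow orchestration: from a gradient of snapshots to a report.

The analysis of a spatial data set starts with one question — are the
patterns periodic? — and routes to different indicator batteries:

* non-periodic data get the generic leading indicators (spatial variance,
  skewness, lag-1 Moran's I) plus spectral reddening; if additionally the
  data are patchy (two phases), the patch-size distribution battery runs
  on the untransformed snapshots;
* periodic isotropic data get the pixel-histogram morphology sequence
  (gaps / labyrinth / spots) and the dominant wavelength;
* periodic anisotropic data get the dominant wavelength trajectory.

Discrete occupancy data are first coarse-grained into local-abundance
counts (default 5x5 blocks) before moment/spectral analysis; the block
size is echoed in the report because it may affect indicator behaviour.
Every reported indicator carries its null band or an explicit
"no valid null" marker, and every trajectory gets a trend statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .grid import GradientSequence, SpatialGrid, coarse_grain
from .indicators import morans_i, spatial_moments
from .nullmodels import (
    coarse_grain_null_test,
    confidence_band,
    spectrum_null_bands,
)
from .patches import (
    classify_periodic_morphology,
    fit_patch_distribution,
    inverse_cumulative,
    patch_sizes,
    _modality,
)
from .spectral import classify_spectrum, periodogram2d, r_spectrum, reddening_index, theta_spectrum
from .trends import trend_statistic

__all__ = ["RoutingDecision", "EWSReport", "route", "run_ews"]


@dataclass(frozen=True)
class RoutingDecision:
    periodic: bool
    isotropic: bool
    patchy: bool
    value_kind: str
    coarse_sub: int
    per_snapshot_periodic: tuple[bool, ...]
    per_snapshot_isotropic: tuple[bool, ...]
    unanimous: bool

    def to_dict(self) -> dict:
        return {
            "periodic": self.periodic,
            "isotropic": self.isotropic,
            "patchy": self.patchy,
            "value_kind": self.value_kind,
            "coarse_sub": self.coarse_sub,
            "per_snapshot_periodic": list(self.per_snapshot_periodic),
            "per_snapshot_isotropic": list(self.per_snapshot_isotropic),
            "unanimous": self.unanimous,
        }


@dataclass
class EWSReport:
    """Structured result of a full early-warning analysis."""

    routing: dict
    indicators: dict
    morphology: list
    patch_analysis: list
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "routing": self.routing,
            "indicators": self.indicators,
            "morphology": self.morphology,
            "patch_analysis": self.patch_analysis,
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_json(cls, payload: str) -> "EWSReport":
        d = json.loads(payload)
        return cls(
            routing=d["routing"],
            indicators=d["indicators"],
            morphology=d["morphology"],
            patch_analysis=d["patch_analysis"],
            provenance=d["provenance"],
        )


def _analysis_grids(seq: GradientSequence, sub: int) -> list[SpatialGrid]:
    """Grids the moment/spectral battery runs on: occupancy data are
    coarse-grained into local-abundance counts first."""
    if seq.value_kind == "discrete_occupancy" and sub > 1:
        return [coarse_grain(g, sub, mode="count") for g in seq]
    return list(seq)


def route(
    seq: GradientSequence,
    sub: int = 5,
    n_sectors: int = 12,
    n_surrogates: int = 200,
    level: float = 0.95,
    seed: int | None = None,
    null_method: Literal["reshuffle", "gaussian", "chi2"] = "chi2",
) -> RoutingDecision:
    """Route a gradient data set to the right indicator battery.

    Periodicity and isotropy are decided per snapshot by comparing the
    r- and theta-spectra against null bands, then combined by majority
    vote across snapshots (disagreements are retained per snapshot and
    flagged).  Patchiness holds for occupancy data with both phases
    present, or for continuous data with a bimodal pixel histogram in a
    majority of snapshots.
    """
    rng = np.random.default_rng(seed)
    grids = _analysis_grids(seq, sub)
    per_p, per_i = [], []
    for g in grids:
        try:
            ps = periodogram2d(g, scale_by_variance=True)
        except Exception:
            per_p.append(False)
            per_i.append(True)
            continue
        rs = r_spectrum(ps)
        angs = theta_spectrum(ps, n_sectors=n_sectors)
        bands = spectrum_null_bands(
            g, n_sectors=n_sectors, method=null_method, n=n_surrogates,
            level=level, rng=rng,
        )
        cls = classify_spectrum(
            rs, angs, bands, grid_extent=min(g.nrows, g.ncols),
        )
        per_p.append(cls.periodic)
        per_i.append(cls.isotropic)
    periodic = sum(per_p) > len(per_p) / 2
    isotropic = sum(per_i) >= len(per_i) / 2
    if seq.value_kind == "discrete_occupancy":
        patchy = any(0.0 < g.values.mean() < 1.0 for g in seq)
    else:
        bimodal = [_modality(g.values.ravel()) >= 2 for g in seq]
        patchy = sum(bimodal) > len(bimodal) / 2
    return RoutingDecision(
        periodic=bool(periodic),
        isotropic=bool(isotropic),
        patchy=bool(patchy),
        value_kind=seq.value_kind,
        coarse_sub=sub if seq.value_kind == "discrete_occupancy" else 1,
        per_snapshot_periodic=tuple(per_p),
        per_snapshot_isotropic=tuple(per_i),
        unanimous=len(set(per_p)) <= 1 and len(set(per_i)) <= 1,
    )


def _trend_dict(values, stress) -> dict:
    arr = np.asarray(values, float)
    if np.sum(~np.isnan(arr)) >= 3 and not np.all(arr[~np.isnan(arr)] == arr[~np.isnan(arr)][0]):
        tr = trend_statistic(arr, method="kendall", stress=stress)
        return {"method": "kendall", "tau": tr.statistic, "p_value": tr.p_value, "n": tr.n}
    return {"method": "kendall", "tau": None, "p_value": None, "n": int(np.sum(~np.isnan(arr)))}


def run_ews(
    seq: GradientSequence,
    sub: int = 5,
    n_sectors: int = 12,
    n_surrogates: int = 200,
    level: float = 0.95,
    seed: int | None = None,
    connectivity: int = 4,
    with_null_bands: bool = True,
) -> EWSReport:
    """Run the routed early-warning battery on a gradient sequence.

    Deterministic under a fixed seed.  Per-snapshot failures are captured
    as null entries rather than aborting the run.
    """
    routing = route(
        seq, sub=sub, n_sectors=n_sectors, n_surrogates=n_surrogates,
        level=level, seed=seed,
    )
    rng = np.random.default_rng(seed)
    grids = _analysis_grids(seq, sub)
    stress = list(seq.stress)
    indicators: dict = {}
    morphology: list = []
    patch_analysis: list = []

    def add_trajectory(name, values, bands):
        indicators[name] = {
            "stress": stress,
            "values": [None if v is None or (isinstance(v, float) and np.isnan(v)) else v
                       for v in values],
            "null_bands": bands,
            "trend": _trend_dict(
                [np.nan if v is None else v for v in values], stress
            ),
        }

    if not routing.periodic:
        # generic leading indicators + reddening
        var_vals, skew_vals, moran_vals, red_vals = [], [], [], []
        var_bands, skew_bands, moran_bands, red_bands = [], [], [], []
        for g in grids:
            m = spatial_moments(g)
            var_vals.append(m.variance)
            skew_vals.append(m.skewness)
            try:
                moran_vals.append(morans_i(g, lag=1).morans_i)
            except Exception:
                moran_vals.append(None)
            try:
                red_vals.append(reddening_index(periodogram2d(g)))
            except Exception:
                red_vals.append(None)
            if with_null_bands:
                try:
                    br = coarse_grain_null_test(
                        g, sub=max(sub, 2), statistic="variance",
                        n=n_surrogates, level=level, rng=rng,
                    )
                    var_bands.append(br.to_dict())
                except Exception as e:
                    var_bands.append({"error": str(e)})
                try:
                    br = coarse_grain_null_test(
                        g, sub=max(sub, 2), statistic="skewness",
                        n=n_surrogates, level=level, rng=rng,
                    )
                    skew_bands.append(br.to_dict())
                except Exception as e:
                    skew_bands.append({"error": str(e)})
                try:
                    br = confidence_band(
                        g, "morans_i", method="reshuffle", n=n_surrogates,
                        level=level, rng=rng,
                    )
                    moran_bands.append(br.to_dict())
                except Exception as e:
                    moran_bands.append({"error": str(e)})
                try:
                    br = confidence_band(
                        g, lambda x: reddening_index(periodogram2d(x)),
                        method="reshuffle", n=n_surrogates, level=level, rng=rng,
                    )
                    red_bands.append(
                        {**br.to_dict(), "statistic": "reddening_index"}
                    )
                except Exception as e:
                    red_bands.append({"error": str(e)})
            else:
                for lst in (var_bands, skew_bands, moran_bands, red_bands):
                    lst.append({"no_valid_null": "bands disabled"})
        add_trajectory("spatial_variance", var_vals, var_bands)
        add_trajectory("spatial_skewness", skew_vals, skew_bands)
        add_trajectory("morans_i_lag1", moran_vals, moran_bands)
        add_trajectory("reddening_index", red_vals, red_bands)

        if routing.patchy:
            for g, s in zip(seq, stress):
                try:
                    sizes = patch_sizes(g, connectivity=connectivity)
                    entry = {
                        "stress": s,
                        "n_patches": int(len(sizes)),
                        "inverse_cumulative": [list(t) for t in inverse_cumulative(sizes)],
                    }
                    try:
                        fits = fit_patch_distribution(sizes)
                        entry["fits"] = [
                            {
                                "family": f.family,
                                "params": f.params,
                                "xmin": f.xmin,
                                "log_likelihood": f.log_likelihood,
                                "aic": f.aic,
                                "n_tail": f.n_tail,
                            }
                            for f in fits
                        ]
                        entry["best_family"] = fits[0].family
                    except ValueError as e:
                        entry["fits"] = None
                        entry["fit_error"] = str(e)
                    patch_analysis.append(entry)
                except Exception as e:
                    patch_analysis.append({"stress": s, "error": str(e)})
    else:
        # periodic branch: dominant wavelength trajectory (+ morphology when
        # isotropic)
        wl_vals, wl_bands = [], []
        for g, s in zip(grids, stress):
            try:
                ps = periodogram2d(g, scale_by_variance=True)
                rs = r_spectrum(ps)
                angs = theta_spectrum(ps, n_sectors=n_sectors)
                bands = spectrum_null_bands(
                    g, n_sectors=n_sectors, method="chi2", level=level, rng=rng
                )
                cls = classify_spectrum(
                    rs, angs, bands, grid_extent=min(g.nrows, g.ncols),
                )
                wl_vals.append(cls.dominant_wavelength)
                wl_bands.append({"no_valid_null": "wavelength is a spectral readout"})
            except Exception as e:
                wl_vals.append(None)
                wl_bands.append({"error": str(e)})
            if routing.isotropic:
                mc = classify_periodic_morphology(g)
                morphology.append(
                    {
                        "stress": s,
                        "morphology": mc.morphology,
                        "histogram_skewness": mc.histogram_skewness,
                        "modality": mc.modality,
                    }
                )
        add_trajectory("dominant_wavelength", wl_vals, wl_bands)

    provenance = {
        "seed": seed,
        "sub": sub,
        "n_sectors": n_sectors,
        "n_surrogates": n_surrogates,
        "level": level,
        "connectivity": connectivity,
        "n_snapshots": len(seq),
        "grid_shape": [seq.snapshots[0].nrows, seq.snapshots[0].ncols],
        "package_version": _version(),
    }
    return EWSReport(
        routing=routing.to_dict(),
        indicators=indicators,
        morphology=morphology,
        patch_analysis=patch_analysis,
        provenance=provenance,
    )


def _version() -> str:
    from . import __version__

    return __version__
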