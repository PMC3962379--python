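# spatialews

Spatial early-warning signals of ecological regime shifts.

Ecosystems with alternative stable states — drylands, shallow lakes,
mussel beds — can cross a tipping point and reorganise abruptly. Because
of critical slowing down, the *spatial* structure of such systems changes
in characteristic ways as the tipping point approaches: fluctuations grow
(spatial variance), become asymmetric (spatial skewness), neighbouring
sites become more alike (spatial correlation), spectral power reddens,
patch-size distributions lose their largest patches, and regular
(Turing-like) patterns walk from gaps through labyrinths to spots.

`spatialews` is a toolbox for ecologists and modellers who have snapshots
of a state variable on a grid — biomass density, NDVI, presence/absence —
ordered along a degradation gradient (in time or in space), and who want
to know whether these indicators are trending, and whether any of it is
statistically distinguishable from chance. It provides:

* **indicators** — spatial moments, Moran's I (`I = (N/W) Σ w_ij z_i z_j
  / Σ z_i²`) at any lag, the 2D periodogram with its radial and angular
  reductions, spectral reddening, patch-size distributions with discrete
  maximum-likelihood fits (power law via Hurwitz-zeta normalisation,
  truncated power law, exponential, lognormal, ranked by AIC), and
  pixel-histogram morphology calls (gaps / labyrinth / spots);
* **null models** — reshuffling and matched-moment Gaussian surrogates,
  the coarse-graining test (the valid null for variance and skewness,
  which plain reshuffling conserves by construction), Monte-Carlo
  confidence bands, and analytic chi-square bands for spectra;
* **trends** — Kendall's tau-b (tie-corrected) or Pearson's r of each
  indicator along the gradient;
* **a workflow router** — periodic or not? isotropic or not? patchy or
  not? — that dispatches a data set to the right indicator battery and
  emits a JSON report with every value, band and trend;
* **three simulators** that generate the reference data sets: a
  biomass–water lattice with a fold-induced collapse, a three-state
  facilitation cellular automaton with scale-free patchiness, and a
  three-PDE scale-dependent-feedback model with Turing patterns.

## Worked example

```python
import numpy as np
from spatialews import (
    simulate_facilitation_ca, coarse_grain, spatial_moments, morans_i,
    coarse_grain_null_test, indicator_trajectory, trend_statistic,
    GradientSequence,
)

# ten occupancy snapshots along an increasing-harshness gradient
seq = simulate_facilitation_ca(grid_size=100, seed=7)

# transform presence/absence into 5x5 local-abundance counts
counts = GradientSequence(
    snapshots=tuple(coarse_grain(g, 5, mode="count") for g in seq),
    stress=seq.stress,
)

var = indicator_trajectory(counts, "variance")
# trend against the degradation rank (the driver b *decreases* along
# the gradient, so rank, not b, encodes "toward the transition")
tau = trend_statistic(var.values, stress=range(1, len(seq) + 1))
print("variance:", np.round(var.values, 2))
print(f"Kendall tau = {tau.statistic:.2f} (p = {tau.p_value:.4f})")

band = coarse_grain_null_test(seq.snapshots[-1], sub=5, statistic="variance",
                              n=200, rng=1, mode="count")
print(f"last snapshot: coarse variance {band.observed:.2f}, "
      f"null band [{band.band.lower:.2f}, {band.band.upper:.2f}], "
      f"significant: {band.significant}")
```

prints

```
variance: [ 4.62  4.95  6.12  6.53  8.54  9.91 11.07 11.78 12.67 14.92]
Kendall tau = 1.00 (p = 0.0000)
last snapshot: coarse variance 14.92, null band [4.01, 5.14], significant: True
```

Spatial variance of the local-abundance field rises monotonically toward
the transition (tau = 1), and the final snapshot's variance sits far
above the coarse-grained reshuffle band — the spatial structure is real,
not a sampling artefact.

The same analysis, routed automatically and with every indicator, band
and trend in one JSON report:

```python
from spatialews import run_ews
report = run_ews(seq, seed=1)
print(report.routing)   # {'periodic': False, 'patchy': True, ...}
```

A command-line interface mirrors the library
(`spatialews simulate | indicators | patches | nulltest | trend | run`);
all file formats are plain text.

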