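# Methods

`spatialews` computes spatial early-warning indicators of ecological
regime shifts on 2D raster snapshots, attaches null-model significance
bands to them, quantifies their trends along degradation gradients, and
ships three stochastic spatial simulators that generate the reference
data sets. This note records the models, the statistical conventions, the
numerical choices, and what the synthetic data do and do not establish.

## The indicator battery

**Generic leading indicators.** Critical slowing down near a bifurcation
lengthens local recovery times; in a spatially extended system this
raises the spatial variance of the state variable, skews its fluctuation
distribution toward the alternative state, and increases coherence
between neighbouring cells. We therefore compute, per snapshot:

* *spatial variance* and *spatial skewness* — population central moments
  (`m2`, `m3/m2^{3/2}`) over all cells. Population rather than
  sample-corrected estimators are used: trend detection only needs
  relative change and the convention is standard in this literature.
  Skewness is reported as *undefined* (not 0) on constant fields;
  reporting 0 would fabricate symmetry information.
* *Moran's I* at lag 1 (rook adjacency) — the cross-product statistic
  `I = (N/W) Σ w_ij z_i z_j / Σ z_i²`, the spatial analogue of lag-1
  autocorrelation. Lags are Manhattan rings for rook weights and
  Chebyshev rings for queen weights; boundaries follow the data topology
  (periodic for simulator output, open for field rasters), and every
  result carries its weights/boundary convention.

**Spectral indicators.** The 2D periodogram is the squared magnitude of
the DFT of the mean-removed field, divided by N, so that its total equals
N·σ² (Parseval) and divided further by N·σ² when variance-scaled, making
snapshots comparable along a gradient. The squared-magnitude convention
(rather than raw DFT magnitude) is used deliberately: Parseval's identity
and the chi-square ordinate theory hold for it, and for peak detection
the two differ only by a monotone rescaling.

The periodogram is stored over the full centred wavenumber plane. The
*r-spectrum* sums power in unit-width concentric rings (ring index
`round(|k|)`, rings above n/2 discarded and reported); the *θ-spectrum*
sums power in equal angular sectors of [0°, 180°), folding conjugate
ordinates (which carry identical power for a real field) modulo 180°.
Nyquist ordinates on even axes are ambiguous modulo n; their power is
split uniformly over the sign representatives of each axis so that
sector powers behave exactly under grid rotation. Both reductions are
exact partitions of the (retained) total power.

*Spectral reddening* is summarised by the fraction of radial power in
rings at or below 20% of the maximum ring — it approaches 1 as variance
concentrates at long wavelengths before a transition.

**Patch-based indicators.** Connected components of occupied cells
(4-connectivity by default, matching the simulators' interaction
neighbourhood; periodic boundaries merge wrap-adjacent components) give
the patch-size distribution, displayed as the inverse cumulative curve
(number of patches ≥ s). Candidate size distributions are fitted by
*discrete* maximum likelihood on the identical tail sample (sizes ≥
xmin, default xmin = 1, Clauset-style KS-optimal xmin available):

* pure power law, normalised by the Hurwitz zeta function;
* power law with exponential cutoff and discretised lognormal,
  normalised by direct summation of the unnormalised mass function until
  the tail contribution is negligible (relative tolerance 1e-12);
* exponential (shifted geometric), with closed-form MLE.

Families are ranked by AIC (`2k − 2·logL`), which handles the non-nested
family set uniformly; least-squares fits of the log inverse cumulative
curve are available for display but never used for ranking, because they
are biased.

**Morphology of periodic patterns.** Along a drying gradient an isotropic
patterned system moves through gaps → labyrinth → spots. The classifier
uses the pixel-value histogram: skewness above +0.2 → spots, below −0.2 →
gaps, near-symmetric histograms → labyrinth if bimodal else homogeneous.
Bimodality is decided by a deterministic 2-component Gaussian-mixture EM
(median-split initialisation) with Ashman's D > 2 and ≥ 10% mass in each
component. The ±0.2 skewness threshold is calibrated so white noise
classifies as homogeneous in ≥ 95% of replicates; histogram skewness
flips sign exactly under value inversion, so gap and spot calls are
mirror images.

## Null models and significance

* **Reshuffle surrogate** — a uniform random permutation of cell values.
  Destroys all spatial structure but conserves the value multiset, hence
  conserves spatial variance and skewness *exactly*: it is a valid null
  for correlation, spectra and patch metrics, and the package refuses it
  (`InvalidNullError`) as a variance/skewness null unless explicitly
  overridden.
* **Gaussian surrogate** — iid normal draws matching the original's mean
  and variance (continuous data only). Valid for skewness, correlation
  and spectra; refused as a variance null (variance is fixed by
  construction).
* **Coarse-graining test** — the discriminating null for variance and
  skewness: compare the statistic on the block-averaged (sub×sub,
  default 5) grid against its distribution over block-averaged
  reshuffles. Averaging blocks of a random matrix shrinks variance by
  sub²; genuine spatial structure survives, so structured grids exceed
  the band. `sub = 1` is allowed but non-discriminating (the
  coarse-grained matrix is the original).

Bands are empirical quantiles over n = 200 surrogates at level 0.95 by
default (indicator nulls are skewed on small grids, so quantiles are
preferred over mean ± z·sd). Coarse-graining truncates trailing
rows/columns that do not fill a block — blocks must be non-overlapping
and equal-sized, and the alternative (padding) would mix block sizes.

**Chi-square spectral bands.** For a structureless field each complex
periodogram ordinate is asymptotically `μ·χ²₂/2`. Bins taken over the
full wavenumber plane contain every conjugate pair twice (P(k) = P(−k)
exactly for real fields), so a bin of m ordinates carries m/2 independent
ones and the mean follows `μ·χ²_m/m`; half-plane binning
(`conjugate_pairs=False`) uses `χ²_{2m}/(2m)`. The analytic bands are
cross-validated against reshuffle-ensemble bands in the test suite and
achieve 95% ± 3 pp empirical coverage on white noise.

**Periodicity and isotropy calls.** Deciding "is any ring above its
band" across ~30 rings at a pointwise 95% level would fire constantly,
and *any* spatial structure (a red spectrum included) exceeds a
white-noise band at low wavenumbers. The classifier therefore uses
family-wise corrected upper limits (Bonferroni for the analytic bands, a
max-statistic quantile for surrogate bands) and calls a snapshot periodic
only when the ring-mean spectrum — smoothed over 3 adjacent rings against
single-periodogram noise — has an interior peak (k ≥ 2) that exceeds the
family-wise limit, exceeds every lower-wavenumber ring (a reddened
spectrum never qualifies), declines toward the next ring, and stands at
least 3× above the lowest ring mean on its low-k side (a broad red
shoulder never qualifies). This keeps the false-positive rate on white
noise below 5% while calling patterned snapshots reliably.

Anisotropy requires a sector to exceed its family-wise limit *and*
dominate (≥ 6× the median sector mean). An isotropic periodic ring
spreads power over all sectors — dominance ratios stay below ~5 even for
strong patterns — while banded patterns concentrate power in one or two
sectors with ratios above ~10.

## Trends

Indicators are evaluated per snapshot along the gradient; undefined
values are flagged and excluded pairwise (never silently dropped or
imputed). The trend statistic is Kendall's τ-b (tie-corrected — indicator
series on discrete data tie frequently) between stress (or rank; τ is
rank-based so they agree for monotone gradients) and indicator value,
with Pearson's r available; p-values follow scipy's exact/asymptotic
switch.

## The three simulated data sets

All three run on periodic lattices, are deterministic under a fixed
seed, and carry their state across driver values (a slow ramp), emitting
one snapshot per driver after a relaxation period. Default driver
gradients are unequally spaced, denser near the transition, and end just
before the collapse.

**1. Local positive feedback lattice** (continuous biomass; no
patchiness). Per cell, biomass grows logistically at a water-limited rate
`r(W) = g₀·W/(W+k_W)` and is lost to saturating grazing `c·B/(B+1)`;
biomass and water diffuse between von Neumann neighbours; water obeys
`dW/dt = R − r_w·W − u·B·W + D_W ∇²W` with rainfall R the driver. The
saturating grazing term makes the bare state locally stable and the
vegetated branch disappear in a fold as rainfall falls (collapse near
R ≈ 0.39 at the default rates g₀=1, K=10, c=1.5, r_w=0.2, u=0.05,
D=0.2). The stochastic forcing on biomass is *additive* (amplitude 0.15)
by default, with a multiplicative option: an additive source keeps the
fluctuation input constant along the gradient, so the rising spatial
variance reflects slowing recovery alone rather than the declining
biomass scale. Euler–Maruyama integration, dt = 0.1, dx = 1.

**2. Facilitation cellular automaton** (discrete occupancy; scale-free
patchiness). Cells are vegetated/empty/degraded. Synchronous updates
with probabilities evaluated on the previous state (reproducible;
an asynchronous random-sequential mode is available): colonisation
`[δρ + (1−δ)q]·max(b − cρ, 0)` with global density ρ and local vegetated
neighbour fraction q (δ = 0.1: mostly local seed rain); mortality m =
0.1; degradation d = 0.1; regeneration `r + f·q` with r = 0.0001 and
facilitation f = 0.9 — the local facilitation that clusters vegetation.
The driver is the establishment probability b (0.90 → 0.33 by default);
vegetation dies out near b ≈ 0.22. With f = 0 *and* fully global
dispersal (δ = 1) the model has no local interactions and its occupancy
is statistically indistinguishable from a reshuffled null — the test
suite uses exactly this neutral configuration (with a nonzero baseline
regeneration so the lattice does not fix), establishing that the spatial
structure is caused by the local terms.

**3. Scale-dependent feedback model** (continuous biomass; periodic
Turing patterns). Three coupled PDE fields — plant biomass P, soil water
W, surface water O — with vegetation-enhanced infiltration
`I(P) = α(P + k₂W₀)/(P + k₂)` concentrating water under patches and fast
surface-water diffusion (D_O = 100 m²/day vs 0.1 for P and W) depleting
it between them: short-range activation, long-range inhibition. At the
default rates the uniform vegetated state is Turing-unstable for rainfall
R between ≈ 1.0 and ≈ 1.25 mm/day with a dominant wavelength of ≈ 45 m
(confirmed against a numerical linear-stability analysis); the patterned
branch persists below 1.0 by hysteresis, walking through gaps →
labyrinth → spots before desertifying. Explicit Euler with a 5-point
Laplacian at dx = 2.5 m (≈ 18 grid points per wavelength), the time step
chosen from the diffusion stability bound (0.8 × dx²/4D_O = 0.0125 day);
a user-supplied dt violating the bound is rejected before integration. A
small additive noise on biomass (0.01, applied at 0.1-day intervals with
amplitude scaled accordingly) continuously seeds the instability, so
patterns form reliably from any starting point in the unstable window.
The inner loops of data sets 1 and 3 are numba-compiled.

## Workflow routing

The first question for any spatial data set is whether its patterns are
periodic; the answer routes the analysis. Occupancy data are first
coarse-grained into 5×5 local-abundance counts (the block size is echoed
in the report, since it can affect indicator behaviour); periodicity and
isotropy are decided per snapshot and combined by majority vote, with
per-snapshot detail retained and a flag when snapshots disagree.
Patchiness means two phases: occupancy data with both phases present, or
continuous data whose pixel histogram is bimodal in a majority of
snapshots (our operationalization; flagged in the report). Non-periodic
data get the generic indicators plus reddening, with the coarse-graining
null for variance/skewness and reshuffle bands for correlation and
reddening; patchy data additionally get the patch battery on the
*untransformed* snapshots; periodic isotropic data get the morphology
sequence and the dominant-wavelength trajectory. Every reported value
carries its band or an explicit no-valid-null marker, every trajectory a
τ, and the JSON report round-trips losslessly.

## Problem sizes

Defaults are chosen so a full desk-scale study runs in minutes on one
core: gradients of 10 snapshots on 100×100 lattices; 200 surrogates per
band; 500 white-noise replicates for calibration; 20 seeds per model for
gradient-level checks; 5,000 draws and 100 replicates for distribution
recovery. The acceptance script (`scripts/acceptance.py`) re-runs all of
these from scratch.

## Known limitations

* The null models are spatially unstructured; nulls with matched
  spatial correlation (Gaussian random fields) are out of scope.
* Periodicity/isotropy thresholds (peak prominence 3, sector dominance
  6, morphology skewness 0.2) are operationalizations of judgements made
  visually in the literature; they are calibrated on white noise and the
  built-in simulators, and may need revisiting for other systems.
* Chi-square ordinate theory is asymptotic and treats the handful of
  self-conjugate (real) ordinates as complex; the test suite's coverage
  checks bound the resulting error at desk scales.
* Indicator trends along a *single* gradient have no replication; the
  skewness trend in particular is noisy at 10 snapshots and its sign
  depends on the direction of the alternative state.
* The simulators emulate the qualitative phenomenology (fold collapse,
  facilitation patchiness, Turing morphology sequence) with canonical
  rate values; they are not calibrated to any field system, so passing
  tests demonstrate internal consistency of the method chain, not
  real-world forecast skill.
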