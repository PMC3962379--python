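"""Periodogram, radial/angular spectra, reddening and classification."""

import numpy as np
import pytest

from spatialews.grid import SpatialGrid
from spatialews.indicators import UndefinedIndicatorError
from spatialews.nullmodels import spectrum_null_bands
from spatialews.spectral import (
    classify_spectrum,
    periodogram2d,
    r_spectrum,
    reddening_index,
    theta_spectrum,
)


def cosine_grid(n=32, kx=3, ky=0):
    x, y = np.meshgrid(np.arange(n), np.arange(n))
    return SpatialGrid(np.cos(2 * np.pi * (kx * x + ky * y) / n))


class TestPeriodogram:
    def test_single_mode_power_in_one_ring(self):
        ps = periodogram2d(cosine_grid(kx=3), scale_by_variance=True)
        rs = r_spectrum(ps)
        assert rs.power[rs.wavenumbers == 3] == pytest.approx(1.0)
        assert rs.power[rs.wavenumbers != 3].sum() == pytest.approx(0.0, abs=1e-12)

    def test_constant_grid(self):
        g = SpatialGrid(np.full((8, 8), 2.0))
        ps = periodogram2d(g, scale_by_variance=False)
        assert ps.total_power == 0.0
        with pytest.raises(UndefinedIndicatorError):
            periodogram2d(g, scale_by_variance=True)

    def test_parseval_on_noise_and_structure(self, rng):
        """Unscaled total power equals N * variance for arbitrary fields."""
        for _ in range(20):
            x = rng.standard_normal((rng.integers(8, 40), rng.integers(8, 40)))
            ps = periodogram2d(SpatialGrid(x), scale_by_variance=False)
            n = x.size
            sigma2 = np.mean((x - x.mean()) ** 2)
            assert ps.total_power == pytest.approx(n * sigma2, rel=1e-10)

    def test_scaled_spectrum_sums_to_one(self, white_noise_grid):
        ps = periodogram2d(white_noise_grid, scale_by_variance=True)
        assert ps.total_power == pytest.approx(1.0, rel=1e-10)

    def test_quadrant_fold_preserves_total(self, white_noise_grid):
        ps = periodogram2d(white_noise_grid)
        assert ps.quadrant.sum() == pytest.approx(ps.total_power, rel=1e-10)
        assert ps.quadrant.shape == (33, 33)


class TestRadialSpectrum:
    def test_partition_of_retained_power(self, white_noise_grid):
        ps = periodogram2d(white_noise_grid)
        rs = r_spectrum(ps)
        assert rs.power.sum() + rs.discarded_power == pytest.approx(
            ps.total_power, rel=1e-10
        )

    def test_white_noise_flat_within_chi2_band(self, rng):
        """Per-ring mean power of white noise stays inside analytic bands
        (all rings, a few replicates)."""
        from spatialews.nullmodels import chi2_spectrum_band

        bad = 0
        total = 0
        for _ in range(20):
            g = SpatialGrid(rng.standard_normal((48, 48)))
            ps = periodogram2d(g)
            rs = r_spectrum(ps)
            mu = ps.total_power / (ps.power.size - 1)
            lo, hi = chi2_spectrum_band(rs.counts, level=0.99, mean_power=mu)
            mean = rs.mean_power
            bad += int(np.sum((mean < lo) | (mean > hi)))
            total += mean.size
        assert bad / total < 0.05


class TestThetaSpectrum:
    def test_vertical_stripes_power_at_zero_degrees(self):
        angs = theta_spectrum(periodogram2d(cosine_grid(kx=3, ky=0)), n_sectors=12)
        assert angs.power[0] == pytest.approx(angs.total_power, rel=1e-10)

    def test_sector_partition(self, white_noise_grid):
        ps = periodogram2d(white_noise_grid)
        angs = theta_spectrum(ps, n_sectors=12)
        assert angs.power.sum() == pytest.approx(ps.total_power, rel=1e-10)

    def test_rotation_permutes_sectors_leaves_rings(self, rng):
        x = rng.standard_normal((32, 32))
        x[:, ::4] += 3.0  # vertical striping, anisotropic
        g = SpatialGrid(x)
        g90 = SpatialGrid(np.rot90(x).copy())
        n_sectors = 12
        a = theta_spectrum(periodogram2d(g), n_sectors=n_sectors)
        b = theta_spectrum(periodogram2d(g90), n_sectors=n_sectors)
        shift = n_sectors // 2  # 90 degrees = half of the [0,180) range
        assert np.allclose(np.roll(a.power, shift), b.power, rtol=1e-8)
        ra = r_spectrum(periodogram2d(g))
        rb = r_spectrum(periodogram2d(g90))
        assert np.allclose(ra.power, rb.power, rtol=1e-8)

    def test_needs_four_sectors(self, white_noise_grid):
        with pytest.raises(ValueError):
            theta_spectrum(periodogram2d(white_noise_grid), n_sectors=2)


class TestReddening:
    def test_lowest_ring_cosine_is_fully_red(self):
        ps = periodogram2d(cosine_grid(n=32, kx=1))
        assert reddening_index(ps, low_fraction=0.2) == pytest.approx(1.0)

    def test_white_noise_matches_ring_count_fraction(self, rng):
        """For a flat spectrum the index estimates the fraction of
        ordinates inside the low-wavenumber disc."""
        vals = []
        for _ in range(30):
            ps = periodogram2d(SpatialGrid(rng.standard_normal((64, 64))))
            vals.append(reddening_index(ps, 0.2))
        rs = r_spectrum(ps)
        cutoff = 0.2 * ps.max_ring
        expected = rs.counts[rs.wavenumbers <= cutoff].sum() / rs.counts.sum()
        assert np.mean(vals) == pytest.approx(expected, abs=0.01)


class TestClassification:
    def test_turing_snapshot_periodic(self, turing_snapshot):
        ps = periodogram2d(turing_snapshot)
        rs, angs = r_spectrum(ps), theta_spectrum(ps)
        bands = spectrum_null_bands(turing_snapshot, method="chi2")
        cls = classify_spectrum(rs, angs, bands, grid_extent=turing_snapshot.nrows)
        assert cls.periodic
        assert cls.dominant_wavenumber is not None and cls.dominant_wavenumber >= 2
        assert cls.dominant_wavelength == pytest.approx(
            turing_snapshot.nrows / cls.dominant_wavenumber
        )

    def test_facilitation_snapshot_not_periodic(self, ca_sequence):
        from spatialews.grid import coarse_grain

        g = coarse_grain(ca_sequence.snapshots[2], 5, mode="count")
        ps = periodogram2d(g)
        bands = spectrum_null_bands(g, method="chi2")
        cls = classify_spectrum(r_spectrum(ps), theta_spectrum(ps), bands)
        assert not cls.periodic

    def test_white_noise_not_periodic_isotropic(self, rng):
        g = SpatialGrid(rng.standard_normal((64, 64)))
        ps = periodogram2d(g)
        bands = spectrum_null_bands(g, method="chi2", level=0.95)
        cls = classify_spectrum(r_spectrum(ps), theta_spectrum(ps), bands)
        assert not cls.periodic
        assert cls.isotropic

    def test_binning_mismatch_rejected(self, white_noise_grid):
        from spatialews.nullmodels import SpectrumBands

        ps = periodogram2d(white_noise_grid)
        rs, angs = r_spectrum(ps), theta_spectrum(ps)
        bad = SpectrumBands(
            radial_lower=np.zeros(3), radial_upper=np.ones(3),
            angular_lower=np.zeros(12), angular_upper=np.ones(12),
            radial_upper_fw=np.ones(3), angular_upper_fw=np.ones(12),
            level=0.95, method="chi2", n_surrogates=0,
        )
        with pytest.raises(ValueError, match="bins"):
            classify_spectrum(rs, angs, bad)
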