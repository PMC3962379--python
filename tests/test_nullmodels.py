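"""Surrogates, confidence bands, the coarse-graining test and chi2 bands."""

import numpy as np
import pytest

from spatialews.grid import SpatialGrid, coarse_grain
from spatialews.indicators import spatial_moments
from spatialews.nullmodels import (
    InvalidNullError,
    chi2_spectrum_band,
    coarse_grain_null_test,
    confidence_band,
    gaussian_surrogate,
    reshuffle_surrogate,
    spectrum_null_bands,
    surrogate_ensemble,
)
from spatialews.spectral import periodogram2d, r_spectrum


class TestReshuffleSurrogate:
    def test_value_multiset_identical(self, rng):
        g = SpatialGrid(rng.random((12, 13)))
        s = reshuffle_surrogate(g, rng)
        assert np.array_equal(np.sort(s.values.ravel()), np.sort(g.values.ravel()))

    def test_variance_and_skewness_conserved_exactly(self, rng):
        g = SpatialGrid(rng.gamma(2.0, 1.0, (15, 15)))
        m0 = spatial_moments(g)
        for _ in range(10):
            m = spatial_moments(reshuffle_surrogate(g, rng))
            # identical multiset; only summation order differs
            assert m.variance == pytest.approx(m0.variance, rel=1e-13)
            assert m.skewness == pytest.approx(m0.skewness, rel=1e-13)

    def test_morans_i_ensemble_centred_on_permutation_mean(self, rng):
        from spatialews.indicators import morans_i

        g = SpatialGrid(rng.random((20, 20)))
        draws = [
            morans_i(reshuffle_surrogate(g, rng), 1).morans_i for _ in range(200)
        ]
        n = g.n_cells
        se = np.std(draws) / np.sqrt(len(draws))
        assert np.mean(draws) == pytest.approx(-1 / (n - 1), abs=4 * se)


class TestGaussianSurrogate:
    def test_mean_unbiased_and_skewness_centred(self, rng):
        g = SpatialGrid(rng.gamma(2.0, 1.0, (20, 20)))
        means, skews = [], []
        for _ in range(300):
            s = gaussian_surrogate(g, rng)
            m = spatial_moments(s)
            means.append(m.mean)
            skews.append(m.skewness)
        assert np.mean(means) == pytest.approx(g.values.mean(), abs=0.02)
        assert np.mean(skews) == pytest.approx(0.0, abs=0.03)

    def test_rejected_for_occupancy_data(self, rng):
        g = SpatialGrid(
            (rng.random((8, 8)) < 0.5).astype(float), value_kind="discrete_occupancy"
        )
        with pytest.raises(InvalidNullError):
            gaussian_surrogate(g, rng)

    def test_rejected_as_variance_null(self, rng):
        g = SpatialGrid(rng.random((10, 10)))
        with pytest.raises(InvalidNullError, match="variance"):
            confidence_band(g, "variance", method="gaussian", rng=rng)


class TestConfidenceBand:
    def test_reshuffle_variance_band_degenerate(self, rng):
        """Reshuffling conserves variance: strict mode refuses, lenient
        mode collapses the band onto the observed value."""
        g = SpatialGrid(rng.random((10, 10)))
        with pytest.raises(InvalidNullError):
            confidence_band(g, "variance", method="reshuffle", rng=rng)
        res = confidence_band(g, "variance", method="reshuffle", rng=rng, strict=False)
        assert res.band.lower == pytest.approx(res.observed, rel=1e-13)
        assert res.band.upper == pytest.approx(res.observed, rel=1e-13)
        assert not res.significant

    def test_clustered_grid_moran_significant(self, ca_sequence):
        g = ca_sequence.snapshots[1]
        res = confidence_band(g, "morans_i", method="reshuffle", n=200, rng=1)
        assert res.significant
        assert res.observed > res.band.upper

    def test_determinism_under_seed(self, rng):
        g = SpatialGrid(rng.random((12, 12)))
        a = confidence_band(g, "morans_i", n=50, rng=42)
        b = confidence_band(g, "morans_i", n=50, rng=42)
        assert a.band.lower == b.band.lower and a.band.upper == b.band.upper

    def test_type_one_error_calibrated(self, rng):
        """On structureless grids the 95% band flags ~5% of cases."""
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            g = SpatialGrid(rng.standard_normal((12, 12)))
            if confidence_band(g, "morans_i", n=100, rng=rng).significant:
                hits += 1
        rate = hits / n_rep
        # 95% band with n=100 surrogates; allow Monte-Carlo slack
        assert 0.005 <= rate <= 0.105


class TestCoarseGrainNullTest:
    def test_iid_grid_inside_band_and_variance_shrinks(self, rng):
        g = SpatialGrid(rng.standard_normal((40, 40)))
        res = coarse_grain_null_test(g, sub=4, statistic="variance", n=200, rng=rng)
        # mean of sub^2 iid values has variance sigma^2 / sub^2
        assert res.observed == pytest.approx(1.0 / 16, rel=0.4)
        assert not res.significant

    def test_clustered_ca_grid_above_band(self, ca_sequence):
        g = ca_sequence.snapshots[2]
        res = coarse_grain_null_test(g, sub=5, statistic="variance", n=200, rng=2)
        assert res.significant
        assert res.observed > res.band.upper

    def test_sub_one_band_collapses_for_variance(self, rng):
        g = SpatialGrid(rng.random((10, 10)))
        res = coarse_grain_null_test(g, sub=1, statistic="variance", n=50, rng=rng)
        assert res.band.lower == pytest.approx(res.observed)
        assert res.band.upper == pytest.approx(res.observed)
        assert not res.significant


class TestChi2Band:
    def test_bands_shrink_with_counts(self):
        lo1, up1 = chi2_spectrum_band([4], mean_power=1.0)
        lo2, up2 = chi2_spectrum_band([64], mean_power=1.0)
        assert up2[0] - lo2[0] < up1[0] - lo1[0]

    def test_coverage_on_white_noise(self, rng):
        """Empirical per-ring coverage of the 95% analytic band."""
        inside = 0
        total = 0
        for _ in range(300):
            ps = periodogram2d(SpatialGrid(rng.standard_normal((32, 32))))
            rs = r_spectrum(ps)
            mu = ps.total_power / (ps.power.size - 1)
            lo, hi = chi2_spectrum_band(rs.counts, level=0.95, mean_power=mu)
            mean = rs.mean_power
            inside += int(np.sum((mean >= lo) & (mean <= hi)))
            total += mean.size
        assert inside / total == pytest.approx(0.95, abs=0.03)

    def test_matches_reshuffle_bands_on_white_noise(self, rng):
        """The analytic construction approximates the surrogate ensemble."""
        g = SpatialGrid(rng.standard_normal((48, 48)))
        chi = spectrum_null_bands(g, method="chi2", level=0.95)
        emp = spectrum_null_bands(g, method="reshuffle", n=400, level=0.95, rng=rng)
        # compare upper limits on interior rings, relative scale
        sel = slice(2, 20)
        ratio = chi.radial_upper[sel] / emp.radial_upper[sel]
        assert np.all(ratio > 0.75) and np.all(ratio < 1.35)


class TestEnsemble:
    def test_ensemble_deterministic_under_seed(self, rng):
        g = SpatialGrid(rng.random((8, 8)))
        e1 = surrogate_ensemble(g, n=5, rng=9)
        e2 = surrogate_ensemble(g, n=5, rng=9)
        for a, b in zip(e1.grids, e2.grids):
            assert np.array_equal(a.values, b.values)
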