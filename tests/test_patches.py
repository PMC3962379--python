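"""Patch labelling, size distributions, MLE fits and morphology."""

import numpy as np
import pytest

from spatialews.grid import SpatialGrid
from spatialews.patches import (
    classify_periodic_morphology,
    fit_patch_distribution,
    inverse_cumulative,
    label_patches,
    patch_sizes,
    sample_discrete_exponential,
    sample_discrete_power_law,
)


def floodfill_sizes(mask, connectivity=4, boundary="open"):
    """Reference BFS component labelling."""
    nr, nc = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    if connectivity == 4:
        offs = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    else:
        offs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    sizes = []
    for i in range(nr):
        for j in range(nc):
            if not mask[i, j] or seen[i, j]:
                continue
            stack = [(i, j)]
            seen[i, j] = True
            size = 0
            while stack:
                a, b = stack.pop()
                size += 1
                for di, dj in offs:
                    x, y = a + di, b + dj
                    if boundary == "periodic":
                        x, y = x % nr, y % nc
                    elif not (0 <= x < nr and 0 <= y < nc):
                        continue
                    if mask[x, y] and not seen[x, y]:
                        seen[x, y] = True
                        stack.append((x, y))
            sizes.append(size)
    return sorted(sizes, reverse=True)


class TestLabelPatches:
    def test_triomino_and_domino(self):
        g = np.zeros((5, 5))
        g[0, 0] = g[1, 0] = g[1, 1] = 1  # L-triomino
        g[3, 3] = g[3, 4] = 1  # domino
        ps = label_patches(g)
        assert sorted(ps.sizes.tolist()) == [2, 3]

    def test_empty_and_full(self):
        assert label_patches(np.zeros((4, 4))).n_patches == 0
        ps = label_patches(np.ones((4, 4)))
        assert ps.n_patches == 1 and ps.sizes[0] == 16

    def test_periodic_wrap_merges(self):
        g = np.zeros((5, 5))
        g[0, 2] = g[4, 2] = 1  # touching across the vertical wrap
        assert label_patches(g, boundary="open").n_patches == 2
        assert label_patches(g, boundary="periodic").n_patches == 1

    def test_connectivity_ordering(self, rng):
        """4-connectivity can only split what 8-connectivity joins."""
        for _ in range(20):
            m = rng.random((20, 20)) < 0.4
            n4 = label_patches(m.astype(float), connectivity=4).n_patches
            n8 = label_patches(m.astype(float), connectivity=8).n_patches
            assert n4 >= n8

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("boundary", ["open", "periodic"])
    def test_matches_floodfill_oracle(self, rng, connectivity, boundary):
        for _ in range(25):
            m = rng.random((15, 15)) < rng.uniform(0.2, 0.7)
            got = patch_sizes(
                m.astype(float), connectivity=connectivity, boundary=boundary
            ).tolist()
            want = floodfill_sizes(m, connectivity, boundary)
            assert got == want

    def test_sizes_conserve_foreground(self, rng):
        m = (rng.random((30, 30)) < 0.45).astype(float)
        ps = label_patches(m)
        assert ps.sizes.sum() == m.sum()

    def test_threshold_required_for_continuous(self, rng):
        with pytest.raises(ValueError, match="threshold"):
            label_patches(rng.random((5, 5)) + 0.001)


class TestInverseCumulative:
    def test_worked_example(self):
        assert inverse_cumulative([1, 1, 2, 5]) == [(1, 4), (2, 2), (5, 1)]

    def test_single_patch(self):
        assert inverse_cumulative([7]) == [(7, 1)]

    def test_counts_non_increasing(self, rng):
        sizes = rng.integers(1, 50, size=200)
        counts = [c for _, c in inverse_cumulative(sizes)]
        assert counts[0] == 200
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty(self):
        assert inverse_cumulative([]) == []


class TestDistributionFits:
    def test_power_law_exponent_recovery(self, rng):
        sizes = sample_discrete_power_law(5000, alpha=2.0, xmin=1, rng=rng)
        fits = fit_patch_distribution(sizes, families=("power_law",))
        assert fits[0].params["exponent"] == pytest.approx(2.0, abs=0.06)

    def test_power_law_ranked_first_on_power_law_sample(self, rng):
        sizes = sample_discrete_power_law(5000, alpha=2.0, xmin=1, rng=rng)
        fits = fit_patch_distribution(
            sizes, families=("power_law", "exponential")
        )
        assert fits[0].family == "power_law"

    def test_exponential_beats_power_law_on_geometric_sample(self, rng):
        sizes = sample_discrete_exponential(5000, rate=0.2, xmin=1, rng=rng)
        fits = fit_patch_distribution(sizes, families=("power_law", "exponential"))
        assert fits[0].family == "exponential"

    def test_aic_consistency(self, rng):
        sizes = sample_discrete_power_law(500, alpha=1.8, xmin=1, rng=rng)
        for f in fit_patch_distribution(sizes):
            assert f.aic == pytest.approx(2 * f.n_params - 2 * f.log_likelihood)
            assert f.n_tail == len(sizes)

    def test_likelihoods_on_identical_tail(self, rng):
        sizes = np.concatenate(
            [np.ones(30, dtype=int), sample_discrete_power_law(300, 2.0, 2, rng=rng)]
        )
        fits = fit_patch_distribution(sizes, xmin=2)
        assert all(f.xmin == 2 for f in fits)
        assert all(f.n_tail == int(np.sum(sizes >= 2)) for f in fits)

    def test_insufficient_tail_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_patch_distribution([1, 2, 3])

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_patch_distribution([3] * 50)

    def test_turing_patches_have_finite_cutoff(self, turing_spots_snapshot):
        """Periodic patterns have a characteristic patch size: the
        truncated power law beats the pure power law."""
        x = turing_spots_snapshot.values
        sizes = patch_sizes(turing_spots_snapshot, threshold=0.5 * (x.min() + x.max()))
        fits = fit_patch_distribution(
            sizes, families=("power_law", "power_law_cutoff")
        )
        assert fits[0].family == "power_law_cutoff"
        assert fits[0].params["rate"] > 0.001


class TestMorphology:
    @staticmethod
    def disc_grid(invert=False, n=64, rng=None):
        rng = rng or np.random.default_rng(5)
        x = np.zeros((n, n))
        yy, xx = np.indices((n, n))
        for _ in range(8):
            cy, cx = rng.integers(0, n, 2)
            d2 = np.minimum(np.abs(yy - cy), n - np.abs(yy - cy)) ** 2 + np.minimum(
                np.abs(xx - cx), n - np.abs(xx - cx)
            ) ** 2
            x[d2 < 16] = 1.0
        x += 0.02 * rng.standard_normal((n, n))
        return SpatialGrid(1.0 - x if invert else x)

    def test_sparse_discs_are_spots(self):
        assert classify_periodic_morphology(self.disc_grid()).morphology == "spots"

    def test_inverted_discs_are_gaps(self):
        assert classify_periodic_morphology(self.disc_grid(invert=True)).morphology == "gaps"

    def test_skewness_flips_sign_under_inversion(self, rng):
        x = rng.gamma(2.0, 1.0, size=(32, 32))
        a = classify_periodic_morphology(SpatialGrid(x))
        b = classify_periodic_morphology(SpatialGrid(x.max() - x))
        assert a.histogram_skewness == pytest.approx(-b.histogram_skewness, rel=1e-9)

    def test_white_noise_homogeneous(self, rng):
        calls = [
            classify_periodic_morphology(SpatialGrid(rng.standard_normal((32, 32))))
            for _ in range(40)
        ]
        frac = np.mean([c.morphology == "homogeneous" for c in calls])
        assert frac >= 0.95

    def test_constant_grid_homogeneous(self):
        c = classify_periodic_morphology(SpatialGrid(np.full((8, 8), 1.0)))
        assert c.morphology == "homogeneous"
        assert c.histogram_skewness == 0.0
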