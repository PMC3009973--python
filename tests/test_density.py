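"""Density grids, overlays and peak-region detection."""

from __future__ import annotations

import numpy as np
import pytest

from proximap import Embedding2D, cluster_overlay, density_grid, peak_regions


def embedding_from_points(points):
    return Embedding2D(
        coords={f"p{i:04d}": (float(x), float(y)) for i, (x, y) in enumerate(points)},
        stress=0.0,
    )


@pytest.fixture(scope="module")
def uniform_cloud():
    rng = np.random.default_rng(31)
    return embedding_from_points(rng.uniform(0, 1, size=(1000, 2)))


class TestCountMode:
    def test_single_point_is_a_point_mass(self):
        emb = embedding_from_points([(0.3, 0.7), (0.9, 0.1)])
        grid = density_grid(emb, {"p0000"}, resolution=(8, 8), mode="count")
        assert grid.values.sum() == 1.0
        assert (grid.values > 0).sum() == 1

    def test_full_subset_conserves_mass(self, uniform_cloud):
        grid = density_grid(uniform_cloud, None, resolution=(16, 16), mode="count")
        assert grid.values.sum() == len(uniform_cloud.coords)

    def test_every_subset_conserves_mass(self, uniform_cloud):
        ids = sorted(uniform_cloud.coords)
        rng = np.random.default_rng(1)
        for size in (1, 7, 123, 999):
            subset = set(rng.choice(ids, size=size, replace=False))
            grid = density_grid(uniform_cloud, subset, resolution=(32, 32), mode="count")
            assert grid.values.sum() == size

    def test_doubling_resolution_preserves_mass(self, uniform_cloud):
        g1 = density_grid(uniform_cloud, None, resolution=(16, 16), mode="count")
        g2 = density_grid(uniform_cloud, None, resolution=(32, 32), mode="count")
        assert g1.values.sum() == g2.values.sum()

    def test_boundary_points_binned(self):
        """Points on the closing edge of the extent land in the last cell."""
        emb = embedding_from_points([(0.0, 0.0), (1.0, 1.0)])
        grid = density_grid(
            emb, None, resolution=(4, 4), mode="count", extent=(0, 1, 0, 1)
        )
        assert grid.values[0, 0] == 1 and grid.values[3, 3] == 1


class TestKdeMode:
    def test_matches_direct_kernel_sum_at_probe_points(self, uniform_cloud):
        """Grid values equal a naive per-point kernel sum at 25 probe cells."""
        h = 0.08
        grid = density_grid(uniform_cloud, None, resolution=(40, 40), mode="kde",
                            bandwidth=h)
        pts = uniform_cloud.array(sorted(uniform_cloud.coords))
        cx, cy = grid.cell_centers()
        rng = np.random.default_rng(7)
        probes = rng.integers(0, 40, size=(25, 2))
        for ix, iy in probes:
            acc = 0.0
            for px, py in pts:  # deliberate slow double loop: the oracle
                r2 = (cx[ix] - px) ** 2 + (cy[iy] - py) ** 2
                acc += np.exp(-r2 / (2 * h * h))
            expect = acc / (len(pts) * 2 * np.pi * h * h)
            assert grid.values[ix, iy] == pytest.approx(expect, abs=1e-9)

    def test_integrates_to_one_with_padded_extent(self, uniform_cloud):
        h = 0.05
        grid = density_grid(
            uniform_cloud, None, resolution=(64, 64), mode="kde", bandwidth=h,
            extent=(-0.3, 1.3, -0.3, 1.3),  # pads data by 6 bandwidths
        )
        assert grid.integral() == pytest.approx(1.0, abs=0.02)

    def test_invariant_to_protein_relabeling(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(50, 2))
        emb_a = embedding_from_points(pts)
        emb_b = Embedding2D(
            coords={f"z{i}": (float(x), float(y)) for i, (x, y) in enumerate(pts)},
            stress=0.0,
        )
        ga = density_grid(emb_a, None, (16, 16), "kde", 0.5)
        gb = density_grid(emb_b, None, (16, 16), "kde", 0.5)
        assert np.array_equal(ga.values, gb.values)

    def test_scott_bandwidth_default_recorded(self, uniform_cloud):
        grid = density_grid(uniform_cloud, None, (16, 16), "kde")
        assert grid.bandwidth is not None and grid.bandwidth > 0

    def test_bad_inputs_rejected(self, uniform_cloud):
        with pytest.raises(ValueError, match="bandwidth"):
            density_grid(uniform_cloud, None, (8, 8), "kde", bandwidth=0.0)
        with pytest.raises(ValueError, match="resolution"):
            density_grid(uniform_cloud, None, (1, 8))
        with pytest.raises(ValueError, match="empty effective subset"):
            density_grid(uniform_cloud, {"not-an-id"}, (8, 8))
        with pytest.raises(ValueError, match="unknown mode"):
            density_grid(uniform_cloud, None, (8, 8), mode="voronoi")


class TestClusterOverlay:
    def test_overlay_mass_bounded_by_background(self, uniform_cloud):
        ids = sorted(uniform_cloud.coords)
        bg, ov = cluster_overlay(uniform_cloud, set(ids), set(ids[:100]),
                                 resolution=(16, 16), mode="count")
        assert ov.values.sum() <= bg.values.sum()
        assert ov.values.sum() == 100

    def test_identical_sets_identical_grids(self, uniform_cloud):
        ids = set(uniform_cloud.coords)
        bg, ov = cluster_overlay(uniform_cloud, ids, ids, resolution=(16, 16))
        assert np.array_equal(bg.values, ov.values)

    def test_grids_share_extent_and_equal_separate_calls(self, uniform_cloud):
        ids = sorted(uniform_cloud.coords)
        subset = set(ids[:50])
        bg, ov = cluster_overlay(uniform_cloud, set(ids), subset,
                                 resolution=(16, 16), mode="count")
        assert bg.extent == ov.extent
        solo = density_grid(uniform_cloud, subset, (16, 16), "count")
        assert np.array_equal(ov.values, solo.values)


def brute_force_regions(mask):
    """Flood-fill oracle for 4-connected component labelling."""
    seen = np.zeros_like(mask, dtype=bool)
    regions = []
    nx_, ny_ = mask.shape
    for i in range(nx_):
        for j in range(ny_):
            if mask[i, j] and not seen[i, j]:
                stack, cells = [(i, j)], []
                seen[i, j] = True
                while stack:
                    x, y = stack.pop()
                    cells.append((x, y))
                    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        u, v = x + dx, y + dy
                        if 0 <= u < nx_ and 0 <= v < ny_ and mask[u, v] and not seen[u, v]:
                            seen[u, v] = True
                            stack.append((u, v))
                regions.append(sorted(cells))
    return regions


class TestPeakRegions:
    def test_point_mass_single_region(self):
        emb = embedding_from_points([(0.5, 0.5)])
        grid = density_grid(emb, None, (8, 8), "count", extent=(0, 1, 0, 1))
        regions = peak_regions(grid, 0.5)
        assert len(regions) == 1 and len(regions[0].cells) == 1

    def test_two_separated_masses_two_regions(self):
        emb = embedding_from_points([(0.1, 0.1), (0.9, 0.9)])
        grid = density_grid(emb, None, (8, 8), "count", extent=(0, 1, 0, 1))
        regions = peak_regions(grid, 0.5)
        assert len(regions) == 2

    def test_gaussian_mixture_matches_flood_fill_oracle(self):
        """Region count and membership on a seeded two-component mixture
        agree with a brute-force flood fill at the same threshold."""
        rng = np.random.default_rng(13)
        pts = np.vstack([
            rng.normal([-2, 0], 0.3, size=(300, 2)),
            rng.normal([2, 0], 0.3, size=(300, 2)),
        ])
        emb = embedding_from_points(pts)
        grid = density_grid(emb, None, (32, 32), "kde", bandwidth=0.3)
        regions = peak_regions(grid, 0.9)
        assert len(regions) == 2
        positive = grid.values[grid.values > 0]
        mask = grid.values >= np.quantile(positive, 0.9)
        oracle = brute_force_regions(mask)
        assert sorted(sorted(r.cells) for r in regions) == sorted(oracle)

    def test_sorted_by_mass_then_top_left(self):
        emb = embedding_from_points([(0.1, 0.1), (0.12, 0.1), (0.9, 0.9)])
        grid = density_grid(emb, None, (4, 4), "count", extent=(0, 1, 0, 1))
        regions = peak_regions(grid, 0.1)
        masses = [r.mass for r in regions]
        assert masses == sorted(masses, reverse=True)

    def test_all_zero_grid_empty_list(self, uniform_cloud):
        grid = density_grid(uniform_cloud, None, (8, 8), "count")
        grid.values[:] = 0.0
        assert peak_regions(grid, 0.5) == []

    def test_quantile_domain_checked(self, uniform_cloud):
        grid = density_grid(uniform_cloud, None, (8, 8), "count")
        with pytest.raises(ValueError, match="quantile"):
            peak_regions(grid, 1.0)
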