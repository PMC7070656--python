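"""Adaptive-kernel density maps: distances, sigmas, rendering, conservation."""

import numpy as np
import pytest

from shoalcount.density import (
    AnnotationSet,
    DensityMap,
    KernelParams,
    adaptive_sigmas,
    block_sum_downsample,
    count_from_density,
    knn_mean_distance,
    read_annotations,
    render_density_map,
    write_annotations,
)


def brute_force_knn_mean(points, k):
    """O(N^2) reference for the mean distance to the k nearest other points."""
    pts = np.asarray(points, dtype=float)
    out = []
    for i in range(len(pts)):
        d = np.sort(np.linalg.norm(pts - pts[i], axis=1))[1:]  # drop self
        out.append(np.nan if d.size == 0 else d[: min(k, d.size)].mean())
    return np.array(out)


class TestKnnMeanDistance:
    def test_two_points_symmetric(self):
        d = knn_mean_distance([[0, 0], [3, 4]], k=1)
        np.testing.assert_allclose(d, [5.0, 5.0])

    def test_collinear_three_points(self):
        # x = 0, 1, 3; k = 2: means are (1+3)/2, (1+2)/2, (2+3)/2
        d = knn_mean_distance([[0, 0], [1, 0], [3, 0]], k=2)
        np.testing.assert_allclose(d, [2.0, 1.5, 2.5])

    def test_single_point_sentinel(self):
        assert np.isnan(knn_mean_distance([[5, 5]], k=3)).all()

    def test_empty_input(self):
        assert knn_mean_distance(np.empty((0, 2)), k=3).size == 0

    @pytest.mark.parametrize("n,k", [(2, 1), (7, 3), (50, 3), (200, 5)])
    def test_matches_brute_force_oracle(self, rng, n, k):
        pts = rng.uniform(0, 100, (n, 2))
        np.testing.assert_allclose(
            knn_mean_distance(pts, k), brute_force_knn_mean(pts, k), atol=1e-12
        )


class TestAdaptiveSigmas:
    def test_beta_scaling(self):
        np.testing.assert_allclose(adaptive_sigmas([10.0], KernelParams(beta=0.3)), [3.0])

    def test_sentinel_maps_to_fallback(self):
        sig = adaptive_sigmas([np.nan], KernelParams(fallback_sigma=15.0))
        np.testing.assert_allclose(sig, [15.0])

    def test_linearity(self, rng):
        d = rng.uniform(1, 50, 20)
        np.testing.assert_allclose(adaptive_sigmas(2 * d), 2 * adaptive_sigmas(d))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            adaptive_sigmas([-1.0])


class TestRenderDensityMap:
    def test_single_center_point_mass_one(self):
        ann = AnnotationSet("a", [[32.0, 32.0]], 64, 64)
        assert count_from_density(render_density_map(ann)) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("n", [5, 40])
    def test_mass_conservation_random_points(self, rng, n):
        ann = AnnotationSet("a", rng.uniform(0, 64, (n, 2)), 64, 64)
        assert count_from_density(render_density_map(ann)) == pytest.approx(n, abs=1e-6)

    def test_border_and_corner_points_renormalized(self):
        # a corner point loses ~3/4 of the untruncated kernel mass to the
        # frame edge; renormalization must restore its contribution to 1
        pts = [[0.0, 0.0], [63.0, 0.0], [0.0, 63.0], [63.0, 63.0], [31.0, 0.0]]
        ann = AnnotationSet("a", pts, 64, 64)
        dmap = render_density_map(ann)
        assert dmap.grid.sum() == pytest.approx(len(pts), abs=1e-6)

    def test_corner_point_would_lose_mass_without_renormalization(self):
        # reference: the analytic in-frame mass of an untruncated Gaussian
        # at the exact corner is ~1/4, so renormalization is doing real work
        ann = AnnotationSet("a", [[0.0, 0.0]], 200, 200)
        params = KernelParams(fallback_sigma=10.0)
        dmap = render_density_map(ann, params)
        raw = np.exp(
            -(np.add.outer(np.arange(200) ** 2, np.arange(200) ** 2))
            / (2 * params.fallback_sigma**2)
        )
        in_frame_fraction = raw.sum() / (2 * np.pi * params.fallback_sigma**2)
        assert dmap.grid.sum() == pytest.approx(1.0, abs=1e-6)
        assert in_frame_fraction < 0.5  # well below 1 before renormalization

    def test_permutation_invariance(self, rng):
        pts = rng.uniform(0, 48, (12, 2))
        ann1 = AnnotationSet("a", pts, 48, 48)
        ann2 = AnnotationSet("a", pts[::-1], 48, 48)
        np.testing.assert_allclose(
            render_density_map(ann1).grid, render_density_map(ann2).grid, atol=1e-12
        )

    def test_out_of_bounds_point_named(self):
        with pytest.raises(ValueError, match="point 1"):
            AnnotationSet("a", [[1.0, 1.0], [70.0, 1.0]], 64, 64)

    def test_sigma_homothety_covariance(self, rng):
        # scaling all coordinates by c scales every mean distance and sigma by c
        pts = rng.uniform(0, 50, (20, 2))
        c = 3.0
        d1 = knn_mean_distance(pts, 3)
        d2 = knn_mean_distance(c * pts, 3)
        np.testing.assert_allclose(d2, c * d1, rtol=1e-12)
        np.testing.assert_allclose(adaptive_sigmas(d2), c * adaptive_sigmas(d1), rtol=1e-12)


class TestBlockSumDownsample:
    def test_factor_one_identity(self, rng):
        dmap = DensityMap(rng.random((8, 8)))
        np.testing.assert_array_equal(block_sum_downsample(dmap, 1).grid, dmap.grid)

    def test_ones_grid(self):
        out = block_sum_downsample(DensityMap(np.ones((4, 4))), 2)
        np.testing.assert_array_equal(out.grid, np.full((2, 2), 4.0))
        assert out.scale == pytest.approx(0.5)

    def test_sum_preserved_factor_eight(self, rng):
        grid = rng.random((64, 64))
        out = block_sum_downsample(DensityMap(grid), 8)
        assert out.grid.sum() == pytest.approx(grid.sum(), abs=1e-12)

    def test_non_divisible_dimensions_zero_padded(self, rng):
        grid = rng.random((10, 13))
        out = block_sum_downsample(DensityMap(grid), 8)
        assert out.grid.shape == (2, 2)
        assert out.grid.sum() == pytest.approx(grid.sum(), abs=1e-12)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            block_sum_downsample(DensityMap(np.ones((4, 4))), 0)

    def test_compose_with_render_preserves_count(self, rng):
        ann = AnnotationSet("a", rng.uniform(0, 60, (17, 2)), 60, 60)
        dmap = render_density_map(ann)
        out = block_sum_downsample(dmap, 8)
        assert out.grid.sum() == pytest.approx(dmap.grid.sum(), abs=1e-12)


class TestCountFromDensity:
    def test_zero_map(self):
        assert count_from_density(DensityMap(np.zeros((5, 5)))) == 0.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            count_from_density(DensityMap(np.array([[1.0, -0.1]])))


class TestAnnotationIO:
    @pytest.mark.parametrize("suffix", [".csv", ".json"])
    def test_round_trip(self, rng, tmp_path, suffix):
        pts = rng.uniform(0, 100, (25, 2))
        ann = AnnotationSet("img7", pts, 100, 120)
        path = tmp_path / f"ann{suffix}"
        write_annotations(ann, path)
        back = read_annotations(path, width=100, height=120)
        assert back.image_id == "img7"
        np.testing.assert_allclose(back.points, ann.points, atol=1e-12)

    def test_empty_csv_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("image_id,x,y\n")
        assert read_annotations(path, width=10, height=10).count == 0

    def test_negative_coordinate_rejected_with_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("image_id,x,y\nimg,5,5\nimg,-1,3\n")
        with pytest.raises(ValueError, match=":3"):
            read_annotations(path, width=10, height=10)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("image_id,col\nimg,5\n")
        with pytest.raises(ValueError, match="'x'"):
            read_annotations(path, width=10, height=10)
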