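import numpy as np
import pytest
from scipy import ndimage

from soycloud import (
    PointCloud,
    kmeans_segment,
    maxmin_init,
    rasterize,
    watershed_segment,
)


def brute_force_maxmin(points, first_idx, k):
    """Exhaustive Max-Min traversal from a known first center."""
    chosen = [first_idx]
    for _ in range(k - 1):
        min_d = np.min(
            np.linalg.norm(points[:, None] - points[chosen][None], axis=2), axis=1
        )
        chosen.append(int(np.argmax(min_d)))
    return points[chosen]


class TestMaxMinInit:
    def test_k1_is_single_random_point(self, rng):
        pts = rng.normal(size=(30, 3))
        centers = maxmin_init(pts, 1, rng_seed=0)
        assert any(np.allclose(centers[0], p) for p in pts)

    def test_collinear_points_pick_extremes_then_middle(self):
        pts = np.column_stack([np.arange(11.0), np.zeros(11), np.zeros(11)])
        # find a seed whose random first pick is the point at 0
        for seed in range(50):
            centers = maxmin_init(pts, 3, rng_seed=seed)
            if centers[0, 0] == 0.0:
                assert centers[1, 0] == 10.0  # farthest from 0
                assert centers[2, 0] == 5.0   # maximizes min distance to {0, 10}
                break
        else:
            pytest.fail("no seed picked x=0 first")

    def test_matches_brute_force_traversal(self, rng):
        pts = rng.uniform(size=(40, 3))
        centers = maxmin_init(pts, 6, rng_seed=3)
        first_idx = int(np.argmax((pts == centers[0]).all(axis=1)))
        np.testing.assert_allclose(centers, brute_force_maxmin(pts, first_idx, 6))

    def test_k_equals_n_selects_every_point(self, rng):
        pts = rng.normal(size=(7, 3))
        centers = maxmin_init(pts, 7, rng_seed=1)
        assert {tuple(c) for c in centers} == {tuple(p) for p in pts}

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(ValueError, match="k"):
            maxmin_init(np.zeros((3, 3)), 4)


class TestKmeansSegment:
    def test_two_distant_blobs_recovered_exactly(self, rng):
        a = rng.normal(size=(200, 3))
        b = rng.normal(size=(250, 3)) + [10.0, 0.0, 0.0]
        cloud = PointCloud(coords=np.vstack([a, b]))
        seg = kmeans_segment(cloud, k=2, rng_seed=0)
        labels = seg.instance_label
        assert len(set(labels[:200])) == 1 and len(set(labels[200:])) == 1
        assert labels[0] != labels[-1]
        # oracle: every point is nearest to its own blob's centroid
        assert seg.n_instances == 2
        assert sorted(seg.counts) == [200, 250]

    def test_k1_centroid_is_mean(self, rng):
        coords = rng.normal(size=(100, 3))
        seg = kmeans_segment(PointCloud(coords=coords), k=1, rng_seed=0)
        assert seg.n_instances == 1
        np.testing.assert_allclose(seg.centroids[0], coords.mean(axis=0))

    def test_duplicate_points_terminate(self):
        coords = np.tile([[1.0, 2.0, 3.0]], (20, 1))
        seg = kmeans_segment(PointCloud(coords=coords), k=2, rng_seed=0)
        assert seg.n_instances >= 1
        assert (seg.instance_label >= 0).all()

    def test_every_point_labeled_and_instances_nonempty(self, rng):
        cloud = PointCloud(coords=rng.normal(size=(300, 3)))
        seg = kmeans_segment(cloud, k=5, rng_seed=2)
        assert (seg.instance_label >= 0).all()
        assert (seg.counts > 0).all()

    def test_wcss_nonincreasing_over_iterations(self, rng):
        coords = rng.normal(size=(400, 3)) * [1, 1, 0.3]
        cloud = PointCloud(coords=coords)

        def wcss(seg):
            return sum(
                float(((coords[seg.instance_label == j] - coords[seg.instance_label == j].mean(axis=0)) ** 2).sum())
                for j in range(seg.n_instances)
            )

        values = [wcss(kmeans_segment(cloud, 4, rng_seed=5, max_iter=i)) for i in (1, 2, 4, 8, 50)]
        assert all(b <= a + 1e-9 for a, b in zip(values, values[1:]))

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kmeans_segment(PointCloud(coords=np.empty((0, 3))), 1)


class TestRasterize:
    def test_single_point_grid_is_padded_3x3(self):
        grid = rasterize(PointCloud(coords=np.array([[0.5, 0.5, 0.0]])), 0.1)
        assert grid.shape == (3, 3)
        assert grid.occupancy.sum() == 1

    def test_point_conservation(self, rng):
        cloud = PointCloud(coords=rng.uniform(size=(250, 3)))
        grid = rasterize(cloud, 0.05)
        assert sum(len(v) for v in grid.point_index().values()) == 250

    def test_matches_brute_force_binning(self, rng):
        coords = rng.uniform(size=(100, 3))
        grid = rasterize(PointCloud(coords=coords), 0.01)
        rows = np.floor((coords[:, 1] - coords[:, 1].min()) / 0.01).astype(int) + 1
        cols = np.floor((coords[:, 0] - coords[:, 0].min()) / 0.01).astype(int) + 1
        np.testing.assert_array_equal(grid.cell_of_point, np.column_stack([rows, cols]))
        expect = np.zeros(grid.shape, dtype=bool)
        expect[rows, cols] = True
        np.testing.assert_array_equal(grid.occupancy, expect)

    def test_nonpositive_resolution_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            rasterize(PointCloud(coords=np.zeros((1, 3))), 0.0)


def disc_cloud(cx, cy, r, n=4000, seed=0):
    rng = np.random.default_rng(seed)
    rad = r * np.sqrt(rng.uniform(size=n))
    ang = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang), np.zeros(n)])


class TestWatershedSegment:
    def test_single_disc_is_one_instance(self):
        cloud = PointCloud(coords=disc_cloud(0, 0, 0.1))
        seg = watershed_segment(cloud, resolution=0.01)
        assert seg.n_instances == 1
        assert (seg.instance_label == 0).all()

    def test_two_overlapping_discs_split_near_equidistance(self):
        # radius 10 cells, centers 18 cells apart -> 2-cell overlap
        c1, c2 = (0.0, 0.0), (0.18, 0.0)
        cloud = PointCloud(
            coords=np.vstack([disc_cloud(*c1, 0.1, seed=1), disc_cloud(*c2, 0.1, seed=2)])
        )
        seg = watershed_segment(cloud, resolution=0.01, marker_min_distance=0.05)
        assert seg.n_instances == 2
        # oracle: nearest-center assignment; disagreements allowed only
        # within one cell of the equidistance line
        d1 = np.linalg.norm(cloud.coords[:, :2] - c1, axis=1)
        d2 = np.linalg.norm(cloud.coords[:, :2] - c2, axis=1)
        labels = seg.instance_label
        lab1 = labels[np.argmin(d1)]
        clear = np.abs(d1 - d2) > 0.02
        expected = np.where(d1 < d2, lab1, 1 - lab1)
        assert (labels[clear] == expected[clear]).all()

    def test_separated_discs_equal_connected_components(self):
        cloud = PointCloud(
            coords=np.vstack([disc_cloud(0, 0, 0.08, seed=3), disc_cloud(0.5, 0, 0.08, seed=4)])
        )
        seg = watershed_segment(cloud, resolution=0.01)
        # oracle: flood-fill labeling of the occupancy image
        grid = rasterize(cloud, 0.01)
        cc, n_cc = ndimage.label(grid.occupancy)
        assert seg.n_instances == n_cc == 2
        cc_pts = cc[grid.cell_of_point[:, 0], grid.cell_of_point[:, 1]]
        # same partition up to label permutation
        for inst in (0, 1):
            assert len(set(cc_pts[seg.instance_label == inst])) == 1

    def test_instance_count_monotone_in_h_depth(self):
        cloud = PointCloud(
            coords=np.vstack([disc_cloud(0, 0, 0.06, seed=5), disc_cloud(0.1, 0, 0.06, seed=6)])
        )
        counts = [
            watershed_segment(cloud, 0.01, marker_min_distance=0.03, h_depth=h).n_instances
            for h in (0.0, 0.01, 0.03, 0.06)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_all_points_labeled_on_scene(self, tiny_scene):
        mask = tiny_scene.cloud.class_label == 1
        plants = tiny_scene.cloud.select(mask)
        seg = watershed_segment(plants)
        assert (seg.instance_label >= 0).all()
        assert (seg.counts > 0).all()

    def test_label_permutation_invariance(self, rng):
        coords = np.vstack([disc_cloud(0, 0, 0.07, seed=7), disc_cloud(0.4, 0, 0.07, seed=8)])
        perm = rng.permutation(len(coords))
        seg_a = watershed_segment(PointCloud(coords=coords), 0.01)
        seg_b = watershed_segment(PointCloud(coords=coords[perm]), 0.01)
        # partition identical after undoing the permutation
        la = seg_a.instance_label[perm]
        lb = seg_b.instance_label
        mapping = {}
        for x, y in zip(la, lb):
            mapping.setdefault(x, y)
            assert mapping[x] == y

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            watershed_segment(PointCloud(coords=np.empty((0, 3))))

    def test_exact_recovery_on_gapped_scene(self, tiny_scene):
        """Simple-category scenes with guaranteed gaps: noiseless variant
        recovers the ground-truth partition exactly."""
        from soycloud import generate_scene

        scene = generate_scene(
            n_rows=1, plants_per_row=3, adhesion="simple", noise_sd=0.0,
            outlier_frac=0.0, points_per_plant=(3000, 4000),
            ground_density=1000, rng_seed=21,
        )
        plants = scene.cloud.select(scene.cloud.class_label == 1)
        seg = watershed_segment(plants, resolution=0.01)
        assert seg.n_instances == 3
        for pid in range(3):
            pred = seg.instance_label[plants.instance_label == pid]
            assert len(set(pred)) == 1
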