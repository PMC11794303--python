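import math

import numpy as np
import pytest

from soycloud import (
    PointCloud,
    TraitConfig,
    build_voxel_grid,
    canopy_cover,
    canopy_roughness,
    canopy_surface_area,
    canopy_volume,
    extract_traits,
    generate_scene,
    plant_height,
    point_ambiguity,
    sweep_voxel_size,
    voxel_occupancy_ratio,
)
from soycloud.traits import VoxelGrid


class TestVoxelGrid:
    def test_layer_count_arithmetic(self, rng):
        # z-extent 0.5 at voxel edge 0.05 -> exactly 10 layers
        coords = rng.uniform(size=(500, 3))
        coords[:, 2] = coords[:, 2] * 0.5
        coords[0, 2], coords[1, 2] = 0.0, 0.5
        grid = build_voxel_grid(PointCloud(coords=coords), 0.05)
        assert grid.P == 10

    def test_interior_fill_radius_clamped_at_zero(self, rng):
        # x-extent 0.5 < 0.59 -> k = 0
        coords = rng.uniform(size=(100, 3)) * [0.5, 0.5, 0.5]
        grid = build_voxel_grid(PointCloud(coords=coords), 0.05)
        assert grid.k == 0.0

    def test_interior_fill_radius_formula(self, rng):
        coords = rng.uniform(size=(200, 3)) * [2.0, 1.0, 0.4]
        coords[0] = [0.0, 0.0, 0.0]
        coords[1] = [2.0, 1.0, 0.4]
        grid = build_voxel_grid(PointCloud(coords=coords), 0.1)
        assert grid.k == pytest.approx((2.0 - 0.59) / 0.1)

    def test_layer_counts_match_brute_force_hashing(self, rng):
        coords = rng.uniform(size=(1000, 3))
        grid = build_voxel_grid(PointCloud(coords=coords), 0.1)
        mins = coords.min(axis=0)
        nx = math.ceil((coords[:, 0].max() - mins[0]) / 0.1)
        ny = math.ceil((coords[:, 1].max() - mins[1]) / 0.1)
        for p in range(grid.P):
            vox = set()
            for x, y, z in coords:
                iz = min(int((z - mins[2]) / 0.1), grid.P - 1)
                if iz == p:
                    vox.add(
                        (min(int((x - mins[0]) / 0.1), nx - 1),
                         min(int((y - mins[1]) / 0.1), ny - 1))
                    )
            assert grid.nT[p] == len(vox)

    def test_oversized_voxel_rejected(self, rng):
        coords = rng.uniform(size=(50, 3)) * [1, 1, 0.05]
        with pytest.raises(ValueError, match="z-extent"):
            build_voxel_grid(PointCloud(coords=coords), 0.5)


class TestVoxelOccupancyRatio:
    def test_saturated_grid_is_one(self):
        grid = VoxelGrid(vos=0.1, P=4, n1=25, nT=np.full(4, 25), k=0.0,
                         bounds=(0, 0.5, 0, 0.5, 0, 0.4))
        assert voxel_occupancy_ratio(grid) == 1.0

    def test_empty_layers_give_zero(self):
        grid = VoxelGrid(vos=0.1, P=3, n1=10, nT=np.zeros(3, dtype=int), k=0.0,
                         bounds=(0, 1, 0, 1, 0, 0.3))
        assert voxel_occupancy_ratio(grid) == 0.0

    def test_two_layer_closed_form_with_fill(self):
        # n1=100, nT=(30,50), k=2: independent arithmetic of the fill term
        grid = VoxelGrid(vos=0.1, P=2, n1=100, nT=np.array([30, 50]), k=2.0,
                         bounds=(0, 1, 0, 1, 0, 0.2))
        expected = (min(30 + 2 * math.pi, 100) + min(50 + 2 * math.pi, 100)) / 200
        assert voxel_occupancy_ratio(grid, interior_fill=True) == pytest.approx(expected)
        assert voxel_occupancy_ratio(grid, interior_fill=False) == pytest.approx(0.4)

    def test_fill_never_decreases_vog(self, rng):
        coords = rng.uniform(size=(2000, 3)) * [1.0, 0.5, 0.4]
        grid = build_voxel_grid(PointCloud(coords=coords), 0.05)
        assert voxel_occupancy_ratio(grid, True) >= voxel_occupancy_ratio(grid, False)


@pytest.fixture(scope="module")
def plant_clouds():
    clouds, areas = [], []
    for s in range(8):
        scene = generate_scene(
            n_rows=1, plants_per_row=1, points_per_plant=(1500, 2000),
            ground_density=500, rng_seed=s,
            size_scale_range=(0.7 + 0.1 * s, 0.7 + 0.1 * s),
        )
        clouds.append(scene.cloud.select(scene.cloud.class_label == 1))
        areas.append(scene.plants[0].true_leaf_area)
    return clouds, np.array(areas)


class TestSweepVoxelSize:
    def test_self_correlation_is_one(self, plant_clouds):
        clouds, _ = plant_clouds
        vogs = np.array(
            [voxel_occupancy_ratio(build_voxel_grid(c, 0.05)) for c in clouds]
        )
        rows = sweep_voxel_size(clouds, vogs, 0.05, 0.05, 0.02)
        assert rows[0]["pearson_r"] == pytest.approx(1.0)

    def test_negated_reference_flips_sign(self, plant_clouds):
        clouds, _ = plant_clouds
        vogs = np.array(
            [voxel_occupancy_ratio(build_voxel_grid(c, 0.05)) for c in clouds]
        )
        rows = sweep_voxel_size(clouds, -vogs, 0.05, 0.05, 0.02)
        assert rows[0]["pearson_r"] == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self, plant_clouds):
        clouds, areas = plant_clouds
        rows = sweep_voxel_size(clouds, areas)
        for row in rows:
            vogs = np.array(
                [voxel_occupancy_ratio(build_voxel_grid(c, row["vos"])) for c in clouds]
            )
            x, y = vogs - vogs.mean(), areas - areas.mean()
            r = (x @ y) / math.sqrt((x @ x) * (y @ y))
            assert row["pearson_r"] == pytest.approx(r, abs=1e-12)
        assert sum(row["best"] for row in rows) == 1

    def test_constant_vog_reports_missing(self):
        cloud = PointCloud(coords=np.random.default_rng(0).uniform(size=(200, 3)))
        rows = sweep_voxel_size([cloud] * 4, np.array([1.0, 2.0, 3.0, 4.0]), 0.1, 0.1, 0.02)
        assert rows[0]["pearson_r"] is None


class TestPointAmbiguity:
    def test_coplanar_cloud_is_zero(self, rng):
        xy = rng.uniform(size=(300, 2))
        cloud = PointCloud(coords=np.column_stack([xy, 0.3 * xy[:, 0] + 0.1 * xy[:, 1]]))
        amb = point_ambiguity(cloud, radius=0.2)
        np.testing.assert_allclose(amb, 0.0, atol=1e-10)

    def test_elevated_point_matches_tls_oracle(self, rng):
        # dense plane patch plus one point at height h above its center
        base = np.column_stack([rng.uniform(-0.02, 0.02, (60, 2)), np.zeros(60)])
        h = 0.01
        coords = np.vstack([base, [0.0, 0.0, h]])
        amb = point_ambiguity(PointCloud(coords=coords), radius=0.05)
        # oracle: smallest-eigenvector plane of the full neighborhood
        mean = coords.mean(axis=0)
        cov = np.cov((coords - mean).T, bias=True)
        w, v = np.linalg.eigh(cov)
        normal = v[:, 0]
        expected = abs((coords[-1] - mean) @ normal)
        assert amb[-1] == pytest.approx(expected, rel=1e-9)
        assert amb[-1] == pytest.approx(h * 60 / 61, rel=0.05)

    def test_singleton_neighborhoods_are_zero(self):
        coords = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 5]], dtype=float)
        amb = point_ambiguity(PointCloud(coords=coords), radius=0.5)
        np.testing.assert_array_equal(amb, 0.0)


class TestCanopyRoughness:
    def test_plane_is_zero(self, rng):
        xy = rng.uniform(size=(200, 2))
        cloud = PointCloud(coords=np.column_stack([xy, np.zeros(200)]))
        assert canopy_roughness(cloud, radius=0.2) == 0.0

    def test_scale_invariance(self, rng):
        coords = rng.normal(size=(400, 3)) * 0.02
        a = canopy_roughness(PointCloud(coords=coords), radius=0.03)
        b = canopy_roughness(PointCloud(coords=coords * 3.0), radius=0.09)
        assert a == pytest.approx(b, rel=1e-9)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(400, 3)) * 0.02
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
        a = canopy_roughness(PointCloud(coords=coords), radius=0.03)
        b = canopy_roughness(PointCloud(coords=coords @ rot.T + [5, -2, 1]), radius=0.03)
        assert a == pytest.approx(b, rel=1e-9)


class TestPlantHeight:
    def test_top_fraction_mean(self):
        coords = np.zeros((10, 3))
        coords[:, 2] = np.arange(0.1, 1.05, 0.1)
        assert plant_height(PointCloud(coords=coords), 0.0) == pytest.approx(0.95)

    def test_constant_height(self):
        coords = np.zeros((20, 3))
        coords[:, 2] = 0.7
        assert plant_height(PointCloud(coords=coords), 0.2) == pytest.approx(0.5)

    def test_translation_invariance(self, rng):
        coords = rng.uniform(size=(100, 3))
        a = plant_height(PointCloud(coords=coords), 0.1)
        shifted = coords + [0, 0, 2.5]
        b = plant_height(PointCloud(coords=shifted), 2.6)
        assert a == pytest.approx(b)


class TestCanopyCover:
    def test_dense_rectangle_converges(self, rng):
        coords = np.column_stack(
            [rng.uniform(0, 2, 100000), rng.uniform(0, 3, 100000), np.zeros(100000)]
        )
        area = canopy_cover(PointCloud(coords=coords), n_bins=100)
        assert area == pytest.approx(6.0, rel=0.02)

    def test_colinear_in_x_is_zero(self):
        coords = np.column_stack([np.zeros(10), np.arange(10.0), np.zeros(10)])
        assert canopy_cover(PointCloud(coords=coords)) == 0.0

    def test_symmetric_square_axis_swap(self, rng):
        coords = np.column_stack(
            [rng.uniform(0, 1, 20000), rng.uniform(0, 1, 20000), np.zeros(20000)]
        )
        swapped = coords[:, [1, 0, 2]]
        a = canopy_cover(PointCloud(coords=coords), 25)
        b = canopy_cover(PointCloud(coords=swapped), 25)
        assert a == pytest.approx(b, rel=0.02)


class TestCanopyVolume:
    def test_dense_unit_box_converges(self, rng):
        coords = rng.uniform(size=(100000, 3))
        vol = canopy_volume(PointCloud(coords=coords), cell_size=0.05)
        assert vol == pytest.approx(1.0, rel=0.02)

    def test_planar_cloud_is_zero(self, rng):
        xy = rng.uniform(size=(500, 2))
        cloud = PointCloud(coords=np.column_stack([xy, np.full(500, 0.4)]))
        assert canopy_volume(cloud, 0.1) == 0.0

    def test_depends_only_on_per_cell_z_range(self, rng):
        xy = rng.uniform(size=(5000, 2))
        z = rng.uniform(size=5000)
        one = PointCloud(coords=np.column_stack([xy, 2 * z]))
        # same footprint, z-range split across two stacked configurations
        stacked = PointCloud(
            coords=np.column_stack([np.vstack([xy, xy]), np.r_[z, z + 1.0]])
        )
        a = canopy_volume(one, 0.1)
        b = canopy_volume(stacked, 0.1)
        assert b >= a  # stacked spans at least the same per-cell range
        top = PointCloud(coords=np.column_stack([xy, np.zeros(5000)]))
        assert canopy_volume(top, 0.1) == 0.0


class TestCanopySurfaceArea:
    def test_flat_unit_square_corners(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        area = canopy_surface_area(PointCloud(coords=coords), max_edge=2.0)
        assert area == pytest.approx(1.0)

    def test_flat_dense_cloud_matches_footprint(self, rng):
        coords = np.column_stack(
            [rng.uniform(0, 1, 30000), rng.uniform(0, 2, 30000), np.zeros(30000)]
        )
        area = canopy_surface_area(PointCloud(coords=coords), max_edge=0.3)
        assert area == pytest.approx(2.0, rel=0.02)

    def test_tilt_multiplies_area_by_sec_theta(self, rng):
        xy = np.column_stack([rng.uniform(0, 1, 40000), rng.uniform(0, 1, 40000)])
        flat = PointCloud(coords=np.column_stack([xy, np.zeros(len(xy))]))
        theta = math.radians(30)
        tilted = PointCloud(
            coords=np.column_stack([xy[:, 0], xy[:, 1], xy[:, 0] * math.tan(theta)])
        )
        a_flat = canopy_surface_area(flat, max_edge=0.3)
        a_tilt = canopy_surface_area(tilted, max_edge=0.3)
        assert a_tilt / a_flat == pytest.approx(1.0 / math.cos(theta), rel=0.02)

    def test_colinear_points_rejected(self):
        coords = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="triangulate"):
            canopy_surface_area(PointCloud(coords=coords), smooth_cell=None)


@pytest.fixture(scope="module")
def plant_cloud():
    scene = generate_scene(
        n_rows=1, plants_per_row=1, points_per_plant=(6000, 8000),
        ground_density=500, noise_sd=0.0, outlier_frac=0.0, rng_seed=5,
    )
    return scene.cloud.select(scene.cloud.class_label == 1)


class TestExtractTraits:
    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_traits(PointCloud(coords=np.empty((0, 3))))

    def test_noiseless_plant_traits_finite(self, plant_cloud):
        tv = extract_traits(plant_cloud, TraitConfig(vos=0.02))
        vals = tv.as_array()
        assert np.all(np.isfinite(vals)) and np.all(vals >= 0)
        assert 0.0 < tv.vog <= 1.0

    def test_scaling_increases_size_traits(self, plant_cloud):
        cfg = TraitConfig(vos=0.02)
        base = extract_traits(plant_cloud, cfg)
        scaled = extract_traits(
            PointCloud(coords=plant_cloud.coords * 1.5), cfg
        )
        assert scaled.height > base.height
        assert scaled.cover > base.cover
        assert scaled.volume > base.volume
        assert scaled.surface_area > base.surface_area
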