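import math

import numpy as np
import pytest

from cropgeobia import (
    GeoTransform,
    ValidationError,
    connected_components,
    detect_seeding_points,
    estimate_k,
    kmeans_centers,
    match_to_reference,
    partition_rows,
    vegetation_mask,
)
from cropgeobia.detection import VegetationComponent
from cropgeobia.performance import run_parallel

from .conftest import segmap_from_label_grid
from .oracles import best_kmeans_objective, flood_fill_mask_components

GT = GeoTransform(0.0, 10.0, 0.1, 0.1)


def component_from_mask(mask, transform=GT, cid=0):
    rr, cc = np.nonzero(mask)
    return VegetationComponent(cid, rr, cc, transform)


class TestVegetationMask:
    def test_all_soil_gives_empty_mask(self):
        grid = np.zeros((4, 4), dtype=np.int32)
        sm = segmap_from_label_grid(grid, GT)
        assert not vegetation_mask(sm, ["Soil"]).any()

    def test_hl_segment_pixel_count_conserved(self):
        grid = np.zeros((5, 5), dtype=np.int32)
        grid.ravel()[:17] = 1
        grid = np.sort(grid.ravel())[::-1].reshape(5, 5)  # 17 ones, contiguous block
        sm = segmap_from_label_grid(grid, GT)
        mask = vegetation_mask(sm, ["Soil", "HL3"])
        assert mask.sum() == 17

    def test_mask_matches_footprint_union_oracle(self):
        rng = np.random.default_rng(0)
        grid = rng.integers(0, 4, (12, 12)).astype(np.int32)
        sm = segmap_from_label_grid(grid, GT)
        labels = ["Soil", "HL1", "Shadow", "HL4"]
        mask = vegetation_mask(sm, labels)
        # oracle: rasterize the union of HL footprint polygons at pixel centers
        import shapely

        veg = [sm.footprints()[i] for i, l in enumerate(labels) if l.startswith("HL")]
        union = shapely.union_all(veg)
        for r in range(12):
            for c in range(12):
                x, y = GT.pixel_to_world(c, r)
                assert mask[r, c] == union.covers(shapely.Point(x, y))

    def test_unlabeled_segment_rejected(self):
        sm = segmap_from_label_grid(np.zeros((2, 2), dtype=np.int32), GT)
        with pytest.raises(ValidationError):
            vegetation_mask(sm, [])


class TestConnectedComponents:
    def test_two_disjoint_blobs(self):
        mask = np.zeros((6, 6), bool)
        mask[0:2, 0:2] = True
        mask[4:6, 4:6] = True
        comps = connected_components(mask, GT)
        assert len(comps) == 2
        assert {c.pixel_count for c in comps} == {4}

    def test_empty_mask(self):
        assert connected_components(np.zeros((5, 5), bool), GT) == []

    def test_diagonal_touch_does_not_connect(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = mask[1, 1] = True
        assert len(connected_components(mask, GT)) == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_random_mask_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((50, 50)) < 0.4
        comps = connected_components(mask, GT)
        oracle = flood_fill_mask_components(mask)
        assert len(comps) == oracle.max() + 1
        for comp in comps:
            ids = {oracle[r, c] for r, c in zip(comp.pixel_rows, comp.pixel_cols)}
            assert len(ids) == 1  # each component is exactly one oracle region
        assert sum(c.pixel_count for c in comps) == mask.sum()

    def test_area_is_pixel_count_times_pixel_area(self):
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:4] = True
        (comp,) = connected_components(mask, GT)
        assert comp.area == pytest.approx(6 * 0.01)


class TestEstimateK:
    d = 0.3

    def test_one_inscribed_circle(self):
        assert estimate_k(math.pi * self.d**2 / 4, self.d) == 1

    def test_four_inscribed_circles(self):
        assert estimate_k(math.pi * self.d**2, self.d) == 4

    def test_fractional_area_rounds_half_up(self):
        # 4*0.1/(pi*0.09) = 1.4147 -> 1
        assert estimate_k(0.1, self.d) == 1
        assert estimate_k(0.107, self.d) == 2  # 1.513 -> 2

    def test_floor_of_one(self):
        assert estimate_k(1e-6, self.d) == 1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            estimate_k(0.0, self.d)
        with pytest.raises(ValidationError):
            estimate_k(1.0, 0.0)


class TestKMeans:
    def test_k1_is_centroid(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(40, 2))
        centers, assign = kmeans_centers(pts, 1, seed=0)
        assert np.allclose(centers[0], pts.mean(axis=0))
        assert (assign == 0).all()

    def test_two_separated_discs_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.3, (50, 2))
        b = rng.normal(0, 0.3, (50, 2)) + [10, 0]
        centers, _ = kmeans_centers(np.vstack([a, b]), 2, seed=0)
        centers = centers[np.argsort(centers[:, 0])]
        assert np.linalg.norm(centers[0] - a.mean(axis=0)) < 1.0
        assert np.linalg.norm(centers[1] - (b.mean(axis=0))) < 1.0

    def test_near_optimal_on_exhaustive_instance(self):
        # two loose groups of four: small enough to enumerate all 2-partitions
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 1.0, (4, 2)), rng.normal(0, 1.0, (4, 2)) + [6, 0]])
        centers, assign = kmeans_centers(pts, 2, seed=0)
        obj = sum(((pts[assign == j] - centers[j]) ** 2).sum() for j in range(2))
        best = best_kmeans_objective(pts, 2)
        assert obj >= best - 1e-9
        assert obj <= 1.05 * best

    def test_fixed_seed_is_bit_identical(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 5, (60, 2))
        c1, a1 = kmeans_centers(pts, 4, seed=9)
        c2, a2 = kmeans_centers(pts, 4, seed=9)
        assert np.array_equal(c1, c2) and np.array_equal(a1, a2)

    def test_k_reduced_when_exceeding_points(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        centers, _ = kmeans_centers(pts, 5, seed=0)
        assert len(centers) == 2


class TestDetectSeedingPoints:
    def test_single_inscribed_circle_yields_centroid(self):
        # disc of area ~pi d^2/4 (d=0.3 m, 0.02 m pixels)
        gt = GeoTransform(0, 2, 0.02, 0.02)
        H = W = 100
        cols, rows = np.meshgrid(np.arange(W), np.arange(H))
        x, y = gt.pixel_to_world(cols, rows)
        mask = np.hypot(x - 1.0, y - 1.0) <= 0.15
        comps = connected_components(mask, gt)
        pts = detect_seeding_points(comps, d=0.3, seed=0)
        assert len(pts) == 1
        assert math.hypot(pts[0].x - 1.0, pts[0].y - 1.0) < 0.02

    def test_empty_component_list(self):
        assert detect_seeding_points([], d=0.3) == []

    def test_degenerate_component_yields_pixel_centroid(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        comps = connected_components(mask, GT)
        (pt,) = detect_seeding_points(comps, d=0.3)
        x, y = GT.pixel_to_world(2, 2)
        assert (pt.x, pt.y) == (x, y)

    def test_point_count_equals_sum_of_k(self):
        rng = np.random.default_rng(5)
        mask = rng.random((40, 40)) < 0.35
        comps = connected_components(mask, GT)
        pts = detect_seeding_points(comps, d=0.3, seed=1)
        expected = sum(
            1 if c.pixel_count < 3 else estimate_k(c.area, 0.3) for c in comps
        )
        assert len(pts) == expected

    def test_small_scene_recovery(self, small_scene):
        from cropgeobia import segment_tiled
        from cropgeobia.synth import truth_segment_labels

        scene = small_scene
        segmap = segment_tiled(scene.raster)
        labels = truth_segment_labels(scene, segmap)
        mask = vegetation_mask(segmap, labels)
        comps = connected_components(mask, scene.raster.transform)
        pts = detect_seeding_points(comps, d=scene.config.d, seed=0)
        det = np.array([[p.x, p.y] for p in pts])
        truth = scene.plant_positions()
        m = match_to_reference(det, truth, scene.config.d / 2)
        assert len(m.pairs) >= 0.9 * len(truth)


class TestPartitionRows:
    def test_two_bands(self):
        m1 = np.zeros((3, 3), bool)
        m1[0, 0] = True
        c1 = component_from_mask(m1, GT, 0)  # y ~ 9.95
        m2 = np.zeros((3, 3), bool)
        m2[2, 2] = True
        c2 = component_from_mask(m2, GT, 1)
        groups = partition_rows([c1, c2], row_pitch=0.2, y_origin=10.0)
        assert len(groups) == 2

    def test_single_row(self):
        comps = [component_from_mask(np.ones((2, 2), bool), GT, i) for i in range(3)]
        groups = partition_rows(comps, row_pitch=None)
        assert list(groups) == [0] and len(groups[0]) == 3

    def test_groups_are_disjoint_and_cover_all(self):
        rng = np.random.default_rng(6)
        mask = rng.random((30, 30)) < 0.3
        comps = connected_components(mask, GT)
        groups = partition_rows(comps, row_pitch=0.5, y_origin=10.0)
        ids = [c.component_id for g in groups.values() for c in g]
        assert sorted(ids) == [c.component_id for c in comps]

    def test_partitioned_detection_equals_serial(self):
        rng = np.random.default_rng(7)
        mask = rng.random((40, 40)) < 0.3
        comps = connected_components(mask, GT)
        serial = detect_seeding_points(comps, d=0.3, seed=42)
        groups = partition_rows(comps, row_pitch=0.4, y_origin=10.0)
        merged, _ = run_parallel(groups, worker_count=1, d=0.3, seed=42)
        key = lambda p: (round(p.x, 9), round(p.y, 9), p.component_id)
        assert sorted(map(key, merged)) == sorted(map(key, serial))
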