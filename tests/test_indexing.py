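import itertools

import numpy as np
import pytest
import shapely

from cropgeobia import (
    ConfigurationError,
    GeoTransform,
    HealthIndexParams,
    SeedingPoint,
    health_index,
    index_all,
    match_to_reference,
    ndvi,
    segments_near_point,
)

from .conftest import make_raster, segmap_from_label_grid

GT = GeoTransform(0.0, 8.0, 1.0, 1.0)


def rect_segmap(n_side=8, seed=0, n_rects=5):
    """Label grid of axis-aligned rectangles over a background segment 0."""
    rng = np.random.default_rng(seed)
    grid = np.zeros((n_side, n_side), dtype=np.int32)
    for lbl in range(1, n_rects + 1):
        r0, c0 = rng.integers(0, n_side - 2, 2)
        h, w = rng.integers(1, 3, 2)
        grid[r0:r0 + h, c0:c0 + w] = lbl
    # background may be split by rectangles; keep only if still labeled 0..n
    labels = np.unique(grid)
    remap = {old: new for new, old in enumerate(labels)}
    grid = np.vectorize(remap.get)(grid).astype(np.int32)
    return segmap_from_label_grid(grid, GT)


class TestSegmentsNearPoint:
    def test_tiny_radius_inside_one_segment(self):
        grid = np.zeros((4, 4), dtype=np.int32)
        grid[:, 2:] = 1
        sm = segmap_from_label_grid(grid, GT)
        assert segments_near_point((0.7, 7.3), 0.05, sm) == {0}

    def test_zero_radius_degenerates_to_containment(self):
        grid = np.zeros((4, 4), dtype=np.int32)
        grid[:, 2:] = 1
        sm = segmap_from_label_grid(grid, GT)
        assert segments_near_point((3.0, 6.0), 0.0, sm) == {1}

    def test_boundary_touch_counts(self):
        grid = np.zeros((4, 4), dtype=np.int32)
        grid[:, 2:] = 1
        sm = segmap_from_label_grid(grid, GT)
        # the shared edge between the two segments lies at x = 2
        assert segments_near_point((1.0, 6.0), 1.0, sm) == {0, 1}

    @pytest.mark.parametrize("seed", range(2))
    def test_matches_pairwise_distance_oracle(self, seed):
        sm = rect_segmap(seed=seed)
        rng = np.random.default_rng(100 + seed)
        footprints = sm.footprints()
        for _ in range(25):
            p = tuple(rng.uniform(0, 8, 2))
            r = float(rng.uniform(0, 2.5))
            got = segments_near_point(p, r, sm)
            expected = {
                i for i, fp in enumerate(footprints)
                if fp.distance(shapely.Point(p)) <= r + 1e-12
            }
            assert got == expected

    def test_radius_monotonicity_of_membership(self):
        sm = rect_segmap(seed=3)
        p = (4.0, 4.0)
        prev = set()
        for r in (0.0, 0.5, 1.0, 2.0, 4.0):
            cur = segments_near_point(p, r, sm)
            assert prev <= cur
            prev = cur


class TestHealthIndex:
    def two_segment_map(self):
        grid = np.zeros((4, 4), dtype=np.int32)
        grid[:, 2:] = 1
        return segmap_from_label_grid(grid, GT)

    def test_uniform_hl3_neighborhood(self):
        sm = self.two_segment_map()
        idx, cls = health_index((2.0, 6.0), sm, ["HL3", "HL3"], HealthIndexParams(r=1.0))
        assert idx == 3.0 and cls == 3

    def test_mean_of_hl2_and_hl4(self):
        sm = self.two_segment_map()
        idx, cls = health_index((2.0, 6.0), sm, ["HL2", "HL4"], HealthIndexParams(r=1.0))
        assert idx == 3.0 and cls == 3

    def test_soil_and_shadow_excluded_by_default(self):
        sm = self.two_segment_map()
        idx, cls = health_index((2.0, 6.0), sm, ["Soil", "HL5"], HealthIndexParams(r=1.0))
        assert idx == 5.0 and cls == 5

    def test_no_qualifying_segment_gives_empty_marker(self):
        sm = self.two_segment_map()
        idx, cls = health_index((2.0, 6.0), sm, ["Soil", "Shadow"], HealthIndexParams(r=1.0))
        assert idx is None and cls is None

    def test_hand_enumerated_rectangles(self):
        # five labeled rectangles; disc at (4, 4) r=2 touches exactly
        # the segments the geometric oracle reports
        sm = rect_segmap(seed=1)
        labels = [f"HL{1 + i % 5}" for i in range(sm.n_segments)]
        p, r = (4.0, 4.0), 2.0
        members = sorted(segments_near_point(p, r, sm))
        by_hand = [i for i, fp in enumerate(sm.footprints())
                   if fp.distance(shapely.Point(p)) <= r]
        assert members == by_hand
        expected = np.mean([1 + i % 5 for i in by_hand])
        idx, _ = health_index(p, sm, labels, HealthIndexParams(r=r))
        assert idx == pytest.approx(expected)

    def test_monotone_under_label_upgrade(self):
        sm = rect_segmap(seed=2)
        labels = ["HL2"] * sm.n_segments
        p, r = (4.0, 4.0), 3.0
        base, _ = health_index(p, sm, labels, HealthIndexParams(r=r))
        for i in sorted(segments_near_point(p, r, sm)):
            up = list(labels)
            up[i] = "HL5"
            idx, _ = health_index(p, sm, up, HealthIndexParams(r=r))
            assert idx >= base

    def test_index_range_when_defined(self):
        sm = rect_segmap(seed=4)
        rng = np.random.default_rng(0)
        labels = [rng.choice(["Soil", "Shadow", "HL1", "HL3", "HL5"]) for _ in range(sm.n_segments)]
        for _ in range(20):
            p = tuple(rng.uniform(0, 8, 2))
            idx, cls = health_index(p, sm, labels, HealthIndexParams(r=float(rng.uniform(0, 2))))
            if idx is not None:
                assert 1.0 <= idx <= 5.0 and 1 <= cls <= 5


class TestIndexAll:
    def test_empty_input(self):
        sm = rect_segmap()
        assert index_all([], sm, ["HL1"] * sm.n_segments) == []

    def test_order_independence(self):
        sm = rect_segmap(seed=5)
        labels = [f"HL{1 + i % 5}" for i in range(sm.n_segments)]
        pts = [SeedingPoint(x, y, 0) for x, y in [(2, 2), (5, 5), (7, 1)]]
        fwd = index_all(pts, sm, labels)
        rev = index_all(pts[::-1], sm, labels)
        assert [(p.x, p.health_index) for p in fwd] == [(p.x, p.health_index) for p in rev][::-1]


class TestNdvi:
    def test_equal_bands_give_zero(self):
        r = make_raster(np.full((4, 3, 3), 5.0), bands=("G", "R", "RE", "NIR"))
        assert np.allclose(ndvi(r), 0.0)

    def test_zero_red_gives_one(self):
        vals = np.full((4, 2, 2), 5.0)
        vals[1] = 0.0
        r = make_raster(vals, bands=("G", "R", "RE", "NIR"))
        assert np.allclose(ndvi(r), 1.0)

    def test_arithmetic_example(self):
        vals = np.zeros((4, 1, 1))
        vals[1] = 0.2
        vals[3] = 0.6
        r = make_raster(vals, bands=("G", "R", "RE", "NIR"))
        assert ndvi(r)[0, 0] == pytest.approx(0.5)

    def test_zero_denominator_is_nodata(self):
        vals = np.zeros((4, 1, 2))
        vals[3, 0, 1] = 1.0
        r = make_raster(vals, bands=("G", "R", "RE", "NIR"))
        out = ndvi(r)
        assert np.isnan(out[0, 0]) and out[0, 1] == 1.0

    def test_missing_band_is_configuration_error(self):
        r = make_raster(np.zeros((2, 2, 2)), bands=("G", "RE"))
        with pytest.raises(ConfigurationError):
            ndvi(r)

    def test_range_invariant_on_random_values(self):
        rng = np.random.default_rng(1)
        r = make_raster(rng.uniform(0, 100, (4, 10, 10)), bands=("G", "R", "RE", "NIR"))
        out = ndvi(r)
        assert np.nanmin(out) >= -1.0 and np.nanmax(out) <= 1.0


class TestMatchToReference:
    def test_exact_detections_pair_perfectly(self):
        ref = np.array([[0, 0], [1, 0], [2, 0]], float)
        m = match_to_reference(ref.copy(), ref, tol=0.15)
        assert len(m.pairs) == 3 and not m.unmatched_reference and not m.spurious_detections

    def test_missing_detections_become_empty(self):
        ref = np.array([[i, 0] for i in range(5)], float)
        det = ref[:3] + 0.01
        m = match_to_reference(det, ref, tol=0.15)
        assert len(m.pairs) == 3 and len(m.unmatched_reference) == 2

    def test_empty_inputs(self):
        m = match_to_reference(np.empty((0, 2)), np.array([[0.0, 0.0]]), 0.1)
        assert m.unmatched_reference == [0]

    @pytest.mark.parametrize("seed", range(3))
    def test_greedy_equals_optimal_on_jittered_layout(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        ref = np.column_stack([np.arange(n) * 1.0, np.zeros(n)])
        det = ref + rng.uniform(-0.1, 0.1, ref.shape)
        keep = rng.random(n) > 0.25
        det = det[keep]
        tol = 0.3
        m = match_to_reference(det, ref, tol)
        # exhaustive optimal assignment oracle: max #pairs, min total distance
        best = None
        for perm in itertools.permutations(range(len(ref)), len(det)):
            dists = [np.linalg.norm(ref[r] - det[d]) for d, r in enumerate(perm)]
            ok = [(r, d) for d, (r, dist) in enumerate(zip(perm, dists)) if dist <= tol]
            cost = sum(d for d in dists if d <= tol)
            cand = (-len(ok), cost, ok)
            if best is None or cand < best:
                best = cand
        assert sorted(m.pairs) == sorted(best[2])
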