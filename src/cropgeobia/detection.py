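"""Seeding-point detection from classified vegetation segments.

Vegetation pixels (segments labeled HL1..HL5) form a binary mask whose
4-connected components approximate individual plants or chains of touching
plants.  Because plants are sown at a known spacing ``d``, a component of area
``a`` holds about ``k = 4 a / (pi d^2)`` plants (the number of inscribed
circles of diameter d); Lloyd's KMeans on the component's pixel coordinates --
spatial information only -- then places the k seeding-point centers, whose
assignment defines a Voronoi tessellation of the component.  Partitioning the
components by plowing row yields groups with no data dependency, which is what
licenses running detection per row in parallel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .classification import HEALTH_CLASSES
from .errors import ValidationError
from .raster import GeoTransform, VectorLayer
from .segmentation import SegmentMap
import shapely

logger = logging.getLogger(__name__)

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])

DEFAULT_SEEDING_DISTANCE = 0.3  # meters between seeding points along a row


@dataclass
class VegetationComponent:
    """One 4-connected region of vegetation pixels."""

    component_id: int
    pixel_rows: np.ndarray
    pixel_cols: np.ndarray
    transform: GeoTransform
    row_id: int = -1

    @property
    def pixel_count(self) -> int:
        return len(self.pixel_rows)

    @property
    def area(self) -> float:
        """Area in m^2: pixel count times pixel area."""
        return self.pixel_count * self.transform.pixel_area

    def world_coords(self) -> np.ndarray:
        x, y = self.transform.pixel_to_world(self.pixel_cols, self.pixel_rows)
        return np.column_stack([x, y])

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.world_coords().mean(axis=0)
        return float(c[0]), float(c[1])


@dataclass
class SeedingPoint:
    """An estimated plant center with its (later filled) health index."""

    x: float
    y: float
    component_id: int
    row_id: int = -1
    cluster_size: int = 0
    health_index: float | None = None
    health_class: int | None = None

    @property
    def center(self) -> tuple[float, float]:
        return (self.x, self.y)


def vegetation_mask(segmap: SegmentMap, labels) -> np.ndarray:
    """Boolean grid, True exactly at pixels of HL-labeled segments.

    ``labels`` maps segment id -> class token (dict or sequence indexed by
    label); every segment must be labeled.
    """
    is_veg = np.zeros(segmap.n_segments, dtype=bool)
    for lbl in range(segmap.n_segments):
        try:
            token = labels[lbl]
        except (KeyError, IndexError):
            raise ValidationError(f"segment {lbl} has no label")
        is_veg[lbl] = token in HEALTH_CLASSES
    grid = segmap.label_grid
    out = np.zeros(grid.shape, dtype=bool)
    valid = grid >= 0
    out[valid] = is_veg[grid[valid]]
    return out


def connected_components(mask: np.ndarray, transform: GeoTransform) -> list[VegetationComponent]:
    """4-connected components of a binary mask, with dense ids in scan order."""
    labeled, n = ndimage.label(np.asarray(mask, dtype=bool), structure=_FOUR_CONN)
    comps = []
    if n:
        objects = ndimage.find_objects(labeled)
        for i in range(n):
            sl = objects[i]
            rr, cc = np.nonzero(labeled[sl] == i + 1)
            comps.append(
                VegetationComponent(i, rr + sl[0].start, cc + sl[1].start, transform)
            )
    return comps


def estimate_k(area_m2: float, d: float = DEFAULT_SEEDING_DISTANCE) -> int:
    """Number of seeding points in a vegetation region: k = 4a/(pi d^2).

    Rounded half-up to an integer with a floor of 1 (a region too small for
    one inscribed circle still came from at least one plant).
    """
    if not (area_m2 > 0):
        raise ValidationError("area must be positive")
    if not (d > 0):
        raise ValidationError("seeding distance d must be positive")
    k = 4.0 * area_m2 / (math.pi * d * d)
    return max(1, int(math.floor(k + 0.5)))


def kmeans_centers(points: np.ndarray, k: int, max_iter: int = 20, seed: int = 0):
    """Lloyd's KMeans on spatial coordinates with deterministic seeded init.

    k-means++ initialization from ``seed``; at most ``max_iter`` Lloyd
    iterations (the within-cluster sum of squares is non-increasing across
    iterations); scikit-learn relocates any emptied cluster to the farthest
    points.  If ``k`` exceeds the number of points it is reduced with a
    warning.  Returns ``(centers (k,2), assignment (n,))``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValidationError("points must be an (n, 2) array")
    if k < 1:
        raise ValidationError("k must be >= 1")
    n = len(points)
    if k > n:
        logger.warning("k=%d exceeds %d points; reducing", k, n)
        k = n
    if k == 1:
        center = points.mean(axis=0)
        return center[None, :], np.zeros(n, dtype=int)
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=max_iter,
        algorithm="lloyd",
        random_state=int(seed) % (2**31),
    ).fit(points)
    return km.cluster_centers_, km.labels_


def _component_seed(base_seed: int, component_id: int) -> int:
    # deterministic per-component stream, independent of grouping order
    return (int(base_seed) * 1000003 + component_id * 7919 + 1) % (2**31)


def detect_seeding_points(
    components: list[VegetationComponent],
    d: float = DEFAULT_SEEDING_DISTANCE,
    max_iter: int = 20,
    seed: int = 0,
) -> list[SeedingPoint]:
    """Estimate seeding-point centers for every vegetation component.

    Per component: k from the area rule, then KMeans on the component's pixel
    world coordinates.  Components of fewer than 3 pixels yield a single point
    at the pixel centroid.  The per-component random stream depends only on
    ``seed`` and the component id, so partitioned runs reproduce serial runs.
    """
    points: list[SeedingPoint] = []
    for comp in components:
        coords = comp.world_coords()
        if comp.pixel_count < 3:
            c = coords.mean(axis=0)
            points.append(
                SeedingPoint(float(c[0]), float(c[1]), comp.component_id, comp.row_id, comp.pixel_count)
            )
            continue
        k = estimate_k(comp.area, d)
        centers, assign = kmeans_centers(coords, k, max_iter, _component_seed(seed, comp.component_id))
        sizes = np.bincount(assign, minlength=len(centers))
        for j, center in enumerate(centers):
            points.append(
                SeedingPoint(
                    float(center[0]), float(center[1]), comp.component_id, comp.row_id, int(sizes[j])
                )
            )
    return points


def partition_rows(
    components: list[VegetationComponent],
    row_pitch: float | None = None,
    y_origin: float = 0.0,
    row_polygons: list | None = None,
) -> dict[int, list[VegetationComponent]]:
    """Group components by plowing row; groups are disjoint and cover all.

    Default model: banding on the world y coordinate with pitch ``row_pitch``
    (row id = round((y_origin - centroid_y)/pitch)).  Explicit ``row_polygons``
    (shapely) override banding; a component straddling rows is assigned to the
    row containing its centroid, logged.
    """
    groups: dict[int, list[VegetationComponent]] = {}
    for comp in components:
        cx, cy = comp.centroid
        if row_polygons is not None:
            rid = -1
            pt = shapely.Point(cx, cy)
            for i, poly in enumerate(row_polygons):
                if poly.covers(pt):
                    rid = i
                    break
            if rid == -1:
                raise ValidationError(f"component {comp.component_id} centroid outside all row polygons")
        elif row_pitch is not None:
            rid = int(round((y_origin - cy) / row_pitch))
        else:
            rid = 0
        comp.row_id = rid
        groups.setdefault(rid, []).append(comp)
    return groups


def points_to_vector_layer(points: list[SeedingPoint], crs_id: str = "unknown") -> VectorLayer:
    feats = []
    for p in points:
        feats.append(
            (
                shapely.Point(p.x, p.y),
                {
                    "component_id": p.component_id,
                    "row_id": p.row_id,
                    "cluster_size": p.cluster_size,
                    "health_index": p.health_index,
                    "health_class": p.health_class,
                },
            )
        )
    return VectorLayer(feats, crs_id)
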