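"""Per-seeding-point health index and NDVI.

The health index at a seeding point p averages the integer health levels of
the segments whose footprints intersect the closed disc B(p, r):

    I(p) = (1/n) * sum_{s in S_{p,r}} I(s)

with r = 7.5 cm by default.  Averaging over a disc of bordering segments
compensates for center-estimation error, mixed reflectance at leaf edges and
occasional misclassified segments.  Soil/Shadow members of S_{p,r} carry no
health level and are excluded from the average by default (keeping I(p) on
the 1-5 scale); an option includes them as zero contributors.  NDVI is the
standard (NIR - R)/(NIR + R) comparison surface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import shapely
from shapely.strtree import STRtree

from .classification import health_value
from .detection import SeedingPoint
from .errors import ConfigurationError, ValidationError
from .raster import MultispectralRaster
from .segmentation import SegmentMap

NULL_CLASS = "EMPTY"  # marker for a seeding point with no surviving plant


@dataclass(frozen=True)
class HealthIndexParams:
    """Disc radius and aggregation choices for I(p)."""

    r: float = 0.075
    include_nonvegetation: bool = False
    discretize: str = "round-half-up"  # or "floor" or "none"

    def __post_init__(self) -> None:
        if not (self.r >= 0):
            raise ValidationError("radius r must be non-negative")
        if self.discretize not in ("round-half-up", "floor", "none"):
            raise ValidationError(f"unknown discretization {self.discretize!r}")


def _disc(p, r: float):
    pt = shapely.Point(p[0], p[1])
    return pt if r == 0 else pt.buffer(r, quad_segs=64)


def segments_near_point(p, r: float, segmap: SegmentMap, tree: STRtree | None = None) -> set[int]:
    """Ids of segments whose footprint intersects the closed disc B(p, r).

    Boundary contact counts as intersection; r = 0 degenerates to the
    segments containing the point itself.
    """
    disc = _disc(p, r)
    footprints = segmap.footprints()
    if tree is None:
        tree = STRtree(footprints)
    hits = tree.query(disc, predicate="intersects")
    return set(int(i) for i in hits)


def _discretize(value: float, how: str):
    if how == "none":
        return value
    if how == "floor":
        return int(np.floor(value))
    return int(np.floor(value + 0.5))  # round-half-up


def health_index(
    p,
    segmap: SegmentMap,
    labels,
    params: HealthIndexParams | None = None,
    tree: STRtree | None = None,
):
    """Health index I(p) and its discretized class.

    Returns ``(index, cls)``; both are None when no qualifying segment
    intersects the disc (the empty marker).
    """
    params = params or HealthIndexParams()
    ids = segments_near_point(p, params.r, segmap, tree)
    values = []
    for sid in sorted(ids):
        hv = health_value(labels[sid])
        if hv is not None:
            values.append(hv)
        elif params.include_nonvegetation:
            values.append(0)
    if not values:
        return None, None
    idx = float(np.mean(values))
    return idx, _discretize(idx, params.discretize)


def index_all(
    points: list[SeedingPoint],
    segmap: SegmentMap,
    labels,
    params: HealthIndexParams | None = None,
) -> list[SeedingPoint]:
    """Annotate every seeding point with I(p) and its class (order-preserving)."""
    params = params or HealthIndexParams()
    tree = STRtree(segmap.footprints())
    out = []
    for p in points:
        idx, cls = health_index((p.x, p.y), segmap, labels, params, tree)
        out.append(replace(p, health_index=idx, health_class=cls))
    return out


def ndvi(raster: MultispectralRaster) -> np.ndarray:
    """Normalized difference vegetation index (NIR - R)/(NIR + R).

    NaN where NIR + R = 0 or at nodata cells; defined values lie in [-1, 1].
    """
    try:
        nir = raster.band("NIR")
        red = raster.band("R")
    except Exception as exc:
        raise ConfigurationError(f"NDVI needs NIR and R bands: {exc}") from exc
    denom = nir + red
    out = np.full(nir.shape, np.nan)
    ok = (denom != 0) & ~raster.nodata_mask
    out[ok] = (nir[ok] - red[ok]) / denom[ok]
    return out


@dataclass
class MatchResult:
    """Greedy nearest-neighbor pairing of detections to reference positions."""

    pairs: list[tuple[int, int]]  # (reference index, detection index)
    unmatched_reference: list[int]  # empty (no-plant) predictions
    spurious_detections: list[int]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def match_to_reference(detected: np.ndarray, reference: np.ndarray, tol: float) -> MatchResult:
    """Pair detections with reference seeding positions within ``tol`` meters.

    Greedy on increasing distance: the globally closest unmatched
    (reference, detection) pair is matched first.  Reference positions left
    unmatched become empty-marker predictions; unmatched detections are
    flagged spurious.
    """
    detected = np.asarray(detected, dtype=float).reshape(-1, 2)
    reference = np.asarray(reference, dtype=float).reshape(-1, 2)
    if len(detected) == 0 or len(reference) == 0:
        return MatchResult([], list(range(len(reference))), list(range(len(detected))))
    dist = np.linalg.norm(reference[:, None, :] - detected[None, :, :], axis=2)
    ri, di = np.nonzero(dist <= tol)
    order = np.argsort(dist[ri, di], kind="stable")
    used_r = np.zeros(len(reference), dtype=bool)
    used_d = np.zeros(len(detected), dtype=bool)
    pairs = []
    for o in order:
        r, d = int(ri[o]), int(di[o])
        if used_r[r] or used_d[d]:
            continue
        used_r[r] = True
        used_d[d] = True
        pairs.append((r, d))
    return MatchResult(
        pairs,
        [i for i in range(len(reference)) if not used_r[i]],
        [i for i in range(len(detected)) if not used_d[i]],
    )
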