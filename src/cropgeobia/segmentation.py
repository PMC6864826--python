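"""Joint spatial-spectral mean-shift segmentation.

Each pixel ``x_i`` is a point in the joint domain (2 spatial + B spectral
coordinates).  Starting from ``y_{i,1} = x_i``, the mode estimate is iterated

    y_{i,j+1} = sum_{x_k in N(y_{i,j})} K(x_k - y_{i,j}) x_k
                / sum_{x_k in N(y_{i,j})} K(x_k - y_{i,j})

where ``N(y)`` contains the pixels within spatial range ``hs`` (pixels) and
spectral range ``hr`` (band units) of ``y``, and ``K`` is a radially symmetric
kernel on the range-normalized joint difference ``u = (ds/hs, dr/hr)``
(Epanechnikov ``max(0, 1-|u|^2)`` by default, Gaussian ``exp(-|u|^2/2)``
selectable).  Iteration stops when the joint displacement drops below
``conv_threshold`` or after ``max_iter`` steps.  Adjacent pixels whose
converged spectral modes agree within a merge tolerance become one segment;
a tiled execution mode handles rasters too large to filter in one piece.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from numba import njit
from scipy import sparse
from scipy.sparse.csgraph import connected_components as _cc

from .errors import ConfigurationError, ValidationError
from .raster import GeoTransform, MultispectralRaster, VectorLayer


@dataclass(frozen=True)
class MeanShiftParams:
    """Mean-shift ranges and merge settings.

    hs, hr
        Spatial range in pixels and spectral range in band units.  The field
        defaults (hs=5, hr=15) suit plant-scale objects on ~4 cm/px imagery
        with band values on a reflectance-like scale.
    kernel
        "epanechnikov" (default) or "gaussian".
    max_iter, conv_threshold
        Iteration cap and joint-displacement stopping threshold.
    min_segment_size
        Segments smaller than this many pixels are merged into the adjacent
        segment with the nearest spectral mode (speckle suppression).
    merge_tol
        Spectral distance below which adjacent converged modes count as "the
        same modal value"; defaults to hr/2.
    """

    hs: float = 5.0
    hr: float = 15.0
    kernel: str = "epanechnikov"
    max_iter: int = 100
    conv_threshold: float = 0.1
    min_segment_size: int = 4
    merge_tol: float | None = None

    def __post_init__(self) -> None:
        if not (self.hs > 0 and self.hr > 0):
            raise ValidationError("hs and hr must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.conv_threshold < 0:
            raise ValidationError("conv_threshold must be non-negative")
        if self.kernel not in ("epanechnikov", "gaussian"):
            raise ValidationError(f"unknown kernel {self.kernel!r}")

    @property
    def effective_merge_tol(self) -> float:
        return self.hr / 2.0 if self.merge_tol is None else self.merge_tol


@dataclass
class ModeGrids:
    """Converged per-pixel modes: spatial (2,H,W) as (x=col, y=row), spectral (B,H,W)."""

    spatial: np.ndarray
    spectral: np.ndarray
    valid: np.ndarray


@njit(cache=True)
def _ms_core(values, valid, hs, hr, gaussian, max_iter, tol):  # pragma: no cover - numba
    B, H, W = values.shape
    sp = np.empty((2, H, W))
    sr = np.empty((B, H, W))
    hs2 = hs * hs
    hr2 = hr * hr
    win = int(math.ceil(hs))
    yr = np.empty(B)
    acc_r = np.empty(B)
    for r in range(H):
        for c in range(W):
            if not valid[r, c]:
                sp[0, r, c] = np.nan
                sp[1, r, c] = np.nan
                for b in range(B):
                    sr[b, r, c] = np.nan
                continue
            ysx = float(c)
            ysy = float(r)
            for b in range(B):
                yr[b] = values[b, r, c]
            for _ in range(max_iter):
                c0 = max(0, int(math.floor(ysx)) - win)
                c1 = min(W - 1, int(math.ceil(ysx)) + win)
                r0 = max(0, int(math.floor(ysy)) - win)
                r1 = min(H - 1, int(math.ceil(ysy)) + win)
                wsum = 0.0
                ax = 0.0
                ay = 0.0
                for b in range(B):
                    acc_r[b] = 0.0
                for rr in range(r0, r1 + 1):
                    for cc in range(c0, c1 + 1):
                        if not valid[rr, cc]:
                            continue
                        ds2 = ((cc - ysx) ** 2 + (rr - ysy) ** 2) / hs2
                        if ds2 > 1.0:
                            continue
                        dr2 = 0.0
                        for b in range(B):
                            d = values[b, rr, cc] - yr[b]
                            dr2 += d * d
                        dr2 /= hr2
                        if dr2 > 1.0:
                            continue
                        u2 = ds2 + dr2
                        if gaussian:
                            w = math.exp(-0.5 * u2)
                        else:
                            w = 1.0 - u2
                            if w <= 0.0:
                                continue
                        wsum += w
                        ax += w * cc
                        ay += w * rr
                        for b in range(B):
                            acc_r[b] += w * values[b, rr, cc]
                if wsum <= 0.0:
                    break
                nx = ax / wsum
                ny = ay / wsum
                disp2 = (nx - ysx) ** 2 + (ny - ysy) ** 2
                ysx = nx
                ysy = ny
                for b in range(B):
                    nb = acc_r[b] / wsum
                    disp2 += (nb - yr[b]) ** 2
                    yr[b] = nb
                if math.sqrt(disp2) < tol:
                    break
            sp[0, r, c] = ysx
            sp[1, r, c] = ysy
            for b in range(B):
                sr[b, r, c] = yr[b]
    return sp, sr


def mean_shift_filter(raster: MultispectralRaster, params: MeanShiftParams | None = None) -> ModeGrids:
    """Run the mode-seeking iteration for every pixel of ``raster``."""
    params = params or MeanShiftParams()
    valid = ~raster.nodata_mask
    vals = raster.values
    if not np.isfinite(vals[:, valid]).all():
        raise ValidationError("raster contains non-finite pixel values")
    sp, sr = _ms_core(
        np.ascontiguousarray(vals),
        np.ascontiguousarray(valid),
        float(params.hs),
        float(params.hr),
        params.kernel == "gaussian",
        int(params.max_iter),
        float(params.conv_threshold),
    )
    return ModeGrids(sp, sr, valid)


# ---------------------------------------------------------------------------
# Mode merging -> segments
# ---------------------------------------------------------------------------


@dataclass
class SegmentMap:
    """A partition of the raster into spatially connected segments.

    ``label_grid`` holds one dense label per non-nodata pixel (-1 for nodata);
    per-segment arrays are indexed by label: ``spatial_modes`` (n,2) in pixel
    (x, y) coordinates, ``spectral_modes`` (n,B) in band units (the feature
    vectors for classification), ``pixel_counts`` (n,).  Polygonal footprints
    in world coordinates are built lazily.
    """

    label_grid: np.ndarray
    spatial_modes: np.ndarray
    spectral_modes: np.ndarray
    pixel_counts: np.ndarray
    transform: GeoTransform
    crs_id: str = "unknown"
    _footprints: list | None = field(default=None, repr=False)

    @property
    def n_segments(self) -> int:
        return len(self.pixel_counts)

    def footprints(self) -> list[shapely.Geometry]:
        """Per-segment polygon footprints (union of pixel cells, world coords)."""
        if self._footprints is None:
            gt = self.transform
            rows, cols = np.nonzero(self.label_grid >= 0)
            labels = self.label_grid[rows, cols]
            x0 = gt.origin_x + cols * gt.pixel_width
            y1 = gt.origin_y - rows * gt.pixel_height
            boxes = shapely.box(x0, y1 - gt.pixel_height, x0 + gt.pixel_width, y1)
            order = np.argsort(labels, kind="stable")
            labels = labels[order]
            boxes = boxes[order]
            bounds = np.searchsorted(labels, np.arange(self.n_segments + 1))
            self._footprints = [
                shapely.union_all(boxes[bounds[i]: bounds[i + 1]]) for i in range(self.n_segments)
            ]
        return self._footprints

    def validate(self, raster: MultispectralRaster | None = None) -> None:
        """Assert the partition invariants; raise ``ValidationError`` on breach."""
        lab = self.label_grid
        n_valid = int((lab >= 0).sum())
        if int(self.pixel_counts.sum()) != n_valid:
            raise ValidationError("pixel counts do not sum to the number of labeled pixels")
        present = np.unique(lab[lab >= 0])
        if len(present) != self.n_segments or (present != np.arange(self.n_segments)).any():
            raise ValidationError("labels are not dense integers 0..n-1")
        # 4-connectivity of every segment
        from scipy import ndimage

        for lbl in range(self.n_segments):
            mask = lab == lbl
            _, num = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
            if num != 1:
                raise ValidationError(f"segment {lbl} is not a single 4-connected component")
        if raster is not None:
            lo = raster.values.min(axis=(1, 2))
            hi = raster.values.max(axis=(1, 2))
            if ((self.spectral_modes < lo - 1e-9) | (self.spectral_modes > hi + 1e-9)).any():
                raise ValidationError("a spectral mode escapes the raster's per-band envelope")

    def to_vector_layer(self, band_names: tuple[str, ...] | None = None) -> VectorLayer:
        band_names = band_names or tuple(f"band{i}" for i in range(self.spectral_modes.shape[1]))
        feats = []
        for lbl, fp in enumerate(self.footprints()):
            attrs = {"label": lbl, "pixel_count": int(self.pixel_counts[lbl])}
            attrs.update(
                {f"mode_{b}": float(v) for b, v in zip(band_names, self.spectral_modes[lbl])}
            )
            feats.append((fp, attrs))
        return VectorLayer(feats, self.crs_id)


def _relabel_scan_order(label_grid: np.ndarray) -> np.ndarray:
    """Relabel to dense integers ordered by first occurrence in raster scan order."""
    flat = label_grid.ravel()
    valid = flat >= 0
    ids = flat[valid]
    first = np.full(ids.max() + 1 if ids.size else 0, -1, dtype=np.int64)
    order = []
    seen = np.zeros(ids.max() + 1 if ids.size else 0, dtype=bool)
    for v in ids:
        if not seen[v]:
            seen[v] = True
            order.append(v)
    for new, old in enumerate(order):
        first[old] = new
    out = label_grid.copy()
    out[label_grid >= 0] = first[label_grid[label_grid >= 0]]
    return out


def _component_labels(modes: ModeGrids, tol: float) -> np.ndarray:
    """4-connected components of the thresholded mode-adjacency graph."""
    valid = modes.valid
    H, W = valid.shape
    idx = np.full((H, W), -1, dtype=np.int64)
    idx[valid] = np.arange(int(valid.sum()))
    n = int(valid.sum())
    sr = modes.spectral
    rows_i = []
    rows_j = []
    # horizontal neighbors
    both = valid[:, :-1] & valid[:, 1:]
    d = np.sqrt(((sr[:, :, :-1] - sr[:, :, 1:]) ** 2).sum(axis=0))
    ok = both & (d <= tol)
    rows_i.append(idx[:, :-1][ok])
    rows_j.append(idx[:, 1:][ok])
    # vertical neighbors
    both = valid[:-1, :] & valid[1:, :]
    d = np.sqrt(((sr[:, :-1, :] - sr[:, 1:, :]) ** 2).sum(axis=0))
    ok = both & (d <= tol)
    rows_i.append(idx[:-1, :][ok])
    rows_j.append(idx[1:, :][ok])
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    g = sparse.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    _, comp = _cc(g, directed=False)
    lab = np.full((H, W), -1, dtype=np.int32)
    lab[valid] = comp
    return _relabel_scan_order(lab)


def _segment_stats(label_grid: np.ndarray, modes: ModeGrids) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    valid = label_grid >= 0
    labels = label_grid[valid]
    n = int(labels.max()) + 1 if labels.size else 0
    counts = np.bincount(labels, minlength=n)
    sp = np.stack(
        [np.bincount(labels, weights=modes.spatial[k][valid], minlength=n) for k in range(2)], axis=1
    )
    sr = np.stack(
        [
            np.bincount(labels, weights=modes.spectral[b][valid], minlength=n)
            for b in range(modes.spectral.shape[0])
        ],
        axis=1,
    )
    with np.errstate(invalid="ignore"):
        sp = sp / counts[:, None]
        sr = sr / counts[:, None]
    return sp, sr, counts


def _merge_small(label_grid: np.ndarray, modes: ModeGrids, min_size: int) -> np.ndarray:
    """Fold segments below ``min_size`` into their spectrally nearest neighbor."""
    if min_size <= 1:
        return label_grid
    lab = label_grid.copy()
    for _ in range(100):
        _, sr, counts = _segment_stats(lab, modes)
        small = np.flatnonzero((counts > 0) & (counts < min_size))
        if small.size == 0 or small.size == np.count_nonzero(counts):
            break
        # adjacency pairs across 4-neighbor boundaries
        pairs = []
        for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
            ok = (a >= 0) & (b >= 0) & (a != b)
            pairs.append(np.stack([a[ok], b[ok]], axis=1))
        pairs = np.concatenate(pairs)
        pairs = np.concatenate([pairs, pairs[:, ::-1]])
        mapping = np.arange(len(counts))
        changed = False
        for s in small:
            nbrs = np.unique(pairs[pairs[:, 0] == s, 1])
            nbrs = nbrs[~np.isin(nbrs, small)] if nbrs.size and (~np.isin(nbrs, small)).any() else nbrs
            if nbrs.size == 0:
                continue
            dist = np.sqrt(((sr[nbrs] - sr[s]) ** 2).sum(axis=1))
            best = nbrs[np.lexsort((nbrs, dist))[0]]  # nearest mode, ties -> lower label
            mapping[s] = best
            changed = True
        if not changed:
            break
        # resolve chains (a small segment may map into another small one)
        for _ in range(len(mapping)):
            nxt = mapping[mapping]
            if (nxt == mapping).all():
                break
            mapping = nxt
        lab = np.where(lab >= 0, mapping[np.maximum(lab, 0)], lab).astype(np.int32)
        lab = _relabel_scan_order(lab)
    return lab


def merge_modes_to_segments(
    raster: MultispectralRaster, modes: ModeGrids, params: MeanShiftParams | None = None
) -> SegmentMap:
    """Group 4-connected pixels with agreeing spectral modes into segments."""
    params = params or MeanShiftParams()
    lab = _component_labels(modes, params.effective_merge_tol)
    lab = _merge_small(lab, modes, params.min_segment_size)
    sp, sr, counts = _segment_stats(lab, modes)
    return SegmentMap(lab, sp, sr, counts, raster.transform, raster.crs_id)


def segment(raster: MultispectralRaster, params: MeanShiftParams | None = None) -> SegmentMap:
    """Untiled convenience path: filter then merge."""
    params = params or MeanShiftParams()
    return merge_modes_to_segments(raster, mean_shift_filter(raster, params), params)


def default_tile_margin(params: MeanShiftParams, tile: int) -> int:
    """Overlap margin bounding the spatial influence of the iteration."""
    return min(int(math.ceil(2 * params.hs * math.sqrt(params.max_iter))), tile // 2)


def segment_tiled(
    raster: MultispectralRaster,
    params: MeanShiftParams | None = None,
    tile: int = 512,
    margin: int | None = None,
) -> SegmentMap:
    """Tiled (large-scale) mean-shift segmentation.

    Each tile is filtered with an overlap margin so that core-region modes are
    unaffected by the tiling; the merged mode grids are then segmented
    globally, which unifies segments crossing tile borders under the same
    merge tolerance as the untiled path.  A raster smaller than one tile takes
    the untiled path exactly.
    """
    params = params or MeanShiftParams()
    if margin is None:
        margin = default_tile_margin(params, tile)
    if tile <= 2 * margin and margin > 0:
        # margin saturated at tile/2 is allowed; anything beyond is a config error
        if tile < 2 * math.ceil(params.hs):
            raise ConfigurationError(f"tile={tile} smaller than the kernel support (hs={params.hs})")
    if tile < 2 * math.ceil(params.hs):
        raise ConfigurationError(f"tile={tile} smaller than the kernel support (hs={params.hs})")
    H, W = raster.shape
    if H <= tile and W <= tile:
        return segment(raster, params)
    sp = np.empty((2, H, W))
    sr = np.empty((raster.n_bands, H, W))
    valid = ~raster.nodata_mask
    for r0 in range(0, H, tile):
        for c0 in range(0, W, tile):
            r1 = min(H, r0 + tile)
            c1 = min(W, c0 + tile)
            rr0 = max(0, r0 - margin)
            cc0 = max(0, c0 - margin)
            rr1 = min(H, r1 + margin)
            cc1 = min(W, c1 + margin)
            sub = MultispectralRaster(
                raster.band_names,
                raster.values[:, rr0:rr1, cc0:cc1],
                raster.transform,
                raster.crs_id,
                raster.nodata_mask[rr0:rr1, cc0:cc1],
            )
            m = mean_shift_filter(sub, params)
            core_r = slice(r0 - rr0, r0 - rr0 + (r1 - r0))
            core_c = slice(c0 - cc0, c0 - cc0 + (c1 - c0))
            sp[0, r0:r1, c0:c1] = m.spatial[0][core_r, core_c] + cc0
            sp[1, r0:r1, c0:c1] = m.spatial[1][core_r, core_c] + rr0
            sr[:, r0:r1, c0:c1] = m.spectral[:, core_r, core_c]
    modes = ModeGrids(sp, sr, valid)
    return merge_modes_to_segments(raster, modes, params)
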