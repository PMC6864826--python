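"""Raster, vector and tabular I/O.

The pipeline's substrate is a 4-band (G, R, RE, NIR) orthomosaic on a regular
north-up grid with an affine geotransform in metric world coordinates.  Rasters
are stored as GeoTIFF-style TIFF files (ModelPixelScale / ModelTiepoint /
GDAL-nodata tags) via :mod:`tifffile`; vector layers use GeoJSON; point
signatures travel as delimited tables.

Coordinate convention: 0-based ``(col, row)`` pixel indices, row 0 at the top,
world coordinates refer to pixel centers, and all geometry predicates operate
in world coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import shapely.geometry as sgeom
import tifffile

from .errors import BandMappingError, RasterIOError, SchemaError, ValidationError

DEFAULT_BANDS: tuple[str, ...] = ("G", "R", "RE", "NIR")

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_NODATA_SENTINEL = -9999.0


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine map between pixel indices and world coordinates.

    ``origin_x, origin_y`` is the world position of the raster's top-left
    corner; ``pixel_width`` and ``pixel_height`` are strictly positive sizes in
    world units (meters for the scenes used here).  World y decreases with the
    row index.
    """

    origin_x: float
    origin_y: float
    pixel_width: float
    pixel_height: float

    def __post_init__(self) -> None:
        if not (self.pixel_width > 0 and self.pixel_height > 0):
            raise ValidationError("pixel size must be strictly positive in both axes")

    def pixel_to_world(self, col, row):
        """World coordinates of the center of pixel ``(col, row)``."""
        col = np.asarray(col, dtype=float)
        row = np.asarray(row, dtype=float)
        x = self.origin_x + (col + 0.5) * self.pixel_width
        y = self.origin_y - (row + 0.5) * self.pixel_height
        return x, y

    def world_to_pixel(self, x, y):
        """Fractional ``(col, row)`` of a world point (inverse of pixel_to_world)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = (x - self.origin_x) / self.pixel_width - 0.5
        row = (self.origin_y - y) / self.pixel_height - 0.5
        return col, row

    def pixel_box(self, col: int, row: int) -> tuple[float, float, float, float]:
        """World-coordinate bounds ``(xmin, ymin, xmax, ymax)`` of one pixel cell."""
        x0 = self.origin_x + col * self.pixel_width
        y1 = self.origin_y - row * self.pixel_height
        return x0, y1 - self.pixel_height, x0 + self.pixel_width, y1

    @property
    def pixel_area(self) -> float:
        return self.pixel_width * self.pixel_height


@dataclass
class MultispectralRaster:
    """Multiband grid of non-negative band values with a geotransform.

    ``values`` has shape ``(n_bands, H, W)``; ``band_names`` gives the band
    order (G, R, RE, NIR by default); ``nodata_mask`` is True where cells carry
    no data.
    """

    band_names: tuple[str, ...]
    values: np.ndarray
    transform: GeoTransform
    crs_id: str = "unknown"
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError("values must have shape (n_bands, H, W)")
        if self.values.shape[0] != len(self.band_names):
            raise ValidationError(
                f"{self.values.shape[0]} band grids for {len(self.band_names)} band names"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape[1:], dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape[1:]:
            raise ValidationError("nodata_mask dimensions must equal band dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    def band(self, name: str) -> np.ndarray:
        try:
            idx = self.band_names.index(name)
        except ValueError:
            raise BandMappingError(f"band {name!r} not present (have {self.band_names})")
        return self.values[idx]


def write_raster(raster: MultispectralRaster, path) -> None:
    """Write a multiband raster as a GeoTIFF-style TIFF file."""
    gt = raster.transform
    data = raster.values.astype(np.float64).copy()
    has_nodata = bool(raster.nodata_mask.any())
    if has_nodata:
        data[:, raster.nodata_mask] = _NODATA_SENTINEL
    desc = json.dumps({"crs_id": raster.crs_id, "bands": list(raster.band_names)})
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (gt.pixel_width, gt.pixel_height, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, gt.origin_x, gt.origin_y, 0.0)),
    ]
    if has_nodata:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(_NODATA_SENTINEL)))
    kwargs = {"planarconfig": "separate"} if data.shape[0] > 1 else {}
    tifffile.imwrite(
        path,
        data if data.shape[0] > 1 else data[0],
        photometric="minisblack",
        description=desc,
        extratags=extratags,
        **kwargs,
    )


def read_raster(path, expected_bands: tuple[str, ...] | None = DEFAULT_BANDS) -> MultispectralRaster:
    """Read a multiband TIFF into a :class:`MultispectralRaster`.

    ``expected_bands`` declares the band set the caller requires; a count
    mismatch raises :class:`BandMappingError` naming the missing bands.  Pass
    ``None`` to accept whatever the file holds.  A missing CRS or geotransform
    is recorded as unknown / identity, not fatal.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            tags = tif.pages[0].tags
            scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
            scale = tuple(scale.value) if scale is not None else None
            tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
            tiepoint = tuple(tiepoint.value) if tiepoint is not None else None
            nodata_tag = tags.get(_TAG_GDAL_NODATA)
            nodata_tag = str(nodata_tag.value) if nodata_tag is not None else None
            desc_tag = tags.get("ImageDescription")
            desc_tag = str(desc_tag.value) if desc_tag is not None else None
    except (OSError, tifffile.TiffFileError) as exc:
        raise RasterIOError(f"cannot read raster {path}: {exc}") from exc
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:
        data = data[None]
    crs_id = "unknown"
    band_names: list[str] | None = None
    if desc_tag is not None:
        try:
            meta = json.loads(desc_tag)
            crs_id = meta.get("crs_id", "unknown")
            band_names = meta.get("bands")
        except (json.JSONDecodeError, AttributeError, TypeError):
            pass
    if band_names is None:
        band_names = [f"band{i + 1}" for i in range(data.shape[0])]
    if expected_bands is not None:
        if data.shape[0] != len(expected_bands):
            missing = [b for b in expected_bands if b not in band_names]
            raise BandMappingError(
                f"expected {len(expected_bands)} bands {tuple(expected_bands)}, "
                f"found {data.shape[0]}; missing: {missing or 'unknown names'}"
            )
        band_names = list(expected_bands)
    if scale is not None and tiepoint is not None:
        sx, sy = float(scale[0]), float(scale[1])
        ox, oy = float(tiepoint[3]), float(tiepoint[4])
        gt = GeoTransform(ox, oy, sx, sy)
    else:
        gt = GeoTransform(0.0, float(data.shape[1]), 1.0, 1.0)
    mask = np.zeros(data.shape[1:], dtype=bool)
    if nodata_tag is not None:
        try:
            nodata_value = float(nodata_tag.strip())
            mask = np.all(data == nodata_value, axis=0)
        except ValueError:
            pass
    return MultispectralRaster(tuple(band_names), data, gt, crs_id, mask)


def write_label_raster(labels: np.ndarray, transform: GeoTransform, path, crs_id="unknown") -> None:
    """Write a single-band integer grid (e.g. a segment label grid)."""
    desc = json.dumps({"crs_id": crs_id, "bands": ["label"]})
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (transform.pixel_width, transform.pixel_height, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.origin_x, transform.origin_y, 0.0)),
    ]
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32), description=desc, extratags=extratags)


def read_label_raster(path) -> tuple[np.ndarray, GeoTransform]:
    r = read_raster(path, expected_bands=None)
    return r.values[0].astype(np.int32), r.transform


# ---------------------------------------------------------------------------
# Vector layers
# ---------------------------------------------------------------------------


@dataclass
class VectorLayer:
    """Georeferenced features: (shapely geometry, attribute dict) pairs."""

    features: list[tuple[shapely.Geometry, dict]] = field(default_factory=list)
    crs_id: str = "unknown"

    def validate(self) -> None:
        keys = None
        for i, (geom, attrs) in enumerate(self.features):
            if not shapely.is_valid(geom):
                raise ValidationError(f"feature {i} has an invalid geometry")
            if keys is None:
                keys = set(attrs)
            elif set(attrs) != keys:
                raise ValidationError(f"feature {i} attribute keys differ from feature 0")

    def __len__(self) -> int:
        return len(self.features)


def write_vector(layer: VectorLayer, path, dialect: str = "geojson", allow_empty: bool = False) -> None:
    """Write a vector layer to disk (GeoJSON dialect)."""
    if dialect != "geojson":
        raise ValidationError(f"unsupported vector dialect {dialect!r}; supported: 'geojson'")
    if not layer.features and not allow_empty:
        raise ValidationError("refusing to write an empty layer (pass allow_empty=True)")
    layer.validate()
    doc = {
        "type": "FeatureCollection",
        "crs_id": layer.crs_id,
        "features": [
            {"type": "Feature", "geometry": sgeom.mapping(geom), "properties": attrs}
            for geom, attrs in layer.features
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_vector(path) -> VectorLayer:
    with open(path) as fh:
        doc = json.load(fh)
    feats = [(sgeom.shape(f["geometry"]), dict(f.get("properties") or {})) for f in doc["features"]]
    return VectorLayer(feats, doc.get("crs_id", "unknown"))


# ---------------------------------------------------------------------------
# Point signatures
# ---------------------------------------------------------------------------


@dataclass
class GeoPointRecord:
    """A georeferenced labeled point, optionally carrying a spectral payload.

    ``x, y`` are lon/lat degrees unless ``projected`` is True, in which case
    they are metric world coordinates (the convention used by the synthetic
    scenes, which live in a local metric CRS).
    """

    x: float
    y: float
    label: str
    projected: bool = False
    payload: np.ndarray | None = None


def read_signatures(path) -> list[GeoPointRecord]:
    """Read a signatures table (CSV) into :class:`GeoPointRecord` objects.

    Requires either ``lon``/``lat`` or projected ``x``/``y`` coordinate
    columns plus a ``label`` column; columns named ``ch000..chNNN`` become the
    per-record payload vector (the portable spectrometer emits 288 channels).
    Rows with non-finite coordinates are reported with their line numbers.
    """
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise SchemaError(f"cannot parse signatures table {path}: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    if "lon" in cols and "lat" in cols:
        xcol, ycol, projected = cols["lon"], cols["lat"], False
    elif "x" in cols and "y" in cols:
        xcol, ycol, projected = cols["x"], cols["y"], True
    else:
        raise SchemaError("missing coordinate columns (need lon/lat or x/y)")
    if "label" not in cols:
        raise SchemaError("missing 'label' column")
    chan_cols = sorted(
        (c for c in df.columns if c.lower().startswith("ch") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )
    xs = pd.to_numeric(df[xcol], errors="coerce")
    ys = pd.to_numeric(df[ycol], errors="coerce")
    bad = ~(np.isfinite(xs.to_numpy()) & np.isfinite(ys.to_numpy()))
    if bad.any():
        lines = [int(i) + 2 for i in np.flatnonzero(bad)]  # +2: header + 1-based
        raise SchemaError(f"non-numeric coordinates at file line(s) {lines}")
    payloads = df[chan_cols].to_numpy(dtype=float) if chan_cols else None
    records = []
    for i in range(len(df)):
        records.append(
            GeoPointRecord(
                float(xs.iloc[i]),
                float(ys.iloc[i]),
                str(df[cols["label"]].iloc[i]),
                projected,
                payloads[i] if payloads is not None else None,
            )
        )
    return records


def write_signatures(records: list[GeoPointRecord], path) -> None:
    rows = []
    for r in records:
        row = {"x" if r.projected else "lon": r.x, "y" if r.projected else "lat": r.y, "label": r.label}
        if r.payload is not None:
            row.update({f"ch{i:03d}": v for i, v in enumerate(r.payload)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
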