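"""End-to-end orchestration: segmentation -> training -> classification ->
seeding-point detection -> health indexing -> validation.

`run_pipeline` composes the stage modules into the full workflow and writes
the standard artifacts (segment layer, classified layer, seeding-point layer,
NDVI raster, summary tables, run log).  Every stage is importable on its own;
this module only wires them together and owns the configuration surface.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import (
    DEFAULT_VOCABULARY,
    ConfusionMatrix,
    MlcModel,
    classify_baseline,
    classify_segments,
    confusion_and_precision,
    fit_mlc,
)
from .detection import (
    SeedingPoint,
    connected_components,
    partition_rows,
    points_to_vector_layer,
    vegetation_mask,
)
from .errors import ConfigurationError, ValidationError
from .indexing import NULL_CLASS, HealthIndexParams, index_all, match_to_reference, ndvi
from .performance import run_parallel
from .raster import (
    GeoPointRecord,
    MultispectralRaster,
    read_raster,
    write_label_raster,
    write_raster,
    write_vector,
)
from .reference import assign_labels
from .segmentation import MeanShiftParams, SegmentMap, segment_tiled

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Effective parameters of one pipeline run (all stages)."""

    segmentation: MeanShiftParams = field(default_factory=MeanShiftParams)
    classifier: str = "mlc"  # mlc | mdm | sam
    priors: str = "uniform"  # uniform | empirical
    d: float = 0.3
    r: float = 0.075
    row_pitch: float | None = None
    row_y_origin: float = 0.0
    tile: int = 512
    margin: int | None = None
    seed: int = 0
    worker_count: int = 1
    match_tol: float | None = None  # defaults to d/2

    def __post_init__(self) -> None:
        if self.classifier not in ("mlc", "mdm", "sam"):
            raise ConfigurationError(f"unknown classifier {self.classifier!r}")
        if self.r >= self.d:
            logger.warning("index radius r=%.3f >= seeding distance d=%.3f", self.r, self.d)

    @property
    def effective_match_tol(self) -> float:
        return self.d / 2 if self.match_tol is None else self.match_tol


@dataclass
class PipelineResult:
    """In-memory artifacts of a full run."""

    raster: MultispectralRaster
    segmap: SegmentMap
    model: MlcModel | None
    segment_labels: list[str]
    points: list[SeedingPoint]
    ndvi: np.ndarray
    confusion: ConfusionMatrix | None
    report: dict | None
    log: list[dict]


def resolve_training_labels(training, segmap: SegmentMap) -> dict[int, str]:
    """Normalize a training source into a segment-id -> label table.

    Accepts a list of georeferenced labeled points (signatures), an existing
    ``{segment id: label}`` mapping, or a callable ``segmap -> mapping``.
    """
    if callable(training):
        training = training(segmap)
    if isinstance(training, dict):
        return {int(k): str(v) for k, v in training.items()}
    if isinstance(training, (list, tuple)) and (not training or isinstance(training[0], GeoPointRecord)):
        return assign_labels(list(training), segmap)
    if isinstance(training, (list, tuple)):
        return {i: str(v) for i, v in enumerate(training)}
    raise ValidationError(f"unsupported training source type {type(training).__name__}")


def run_pipeline(
    raster,
    training,
    cfg: PipelineConfig | None = None,
    out_dir=None,
    reference_positions=None,
    reference_classes=None,
) -> PipelineResult:
    """Run the full workflow and optionally write every artifact to ``out_dir``.

    ``reference_positions``/``reference_classes`` (expected seeding-point
    layout and its truth classes, EMPTY/None for dead points) enable the
    validation stage.
    """
    cfg = cfg or PipelineConfig()
    log: list[dict] = []

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc
        log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
        return out

    if not isinstance(raster, MultispectralRaster):
        raster = _stage("read", lambda: read_raster(raster))

    segmap = _stage(
        "segmentation", lambda: segment_tiled(raster, cfg.segmentation, cfg.tile, cfg.margin)
    )
    log[-1]["n_segments"] = segmap.n_segments

    train_table = _stage("training", lambda: resolve_training_labels(training, segmap))
    if not train_table:
        raise ValidationError("[stage training] no labeled training segments")
    ids = sorted(train_table)
    feats = segmap.spectral_modes[ids]
    toks = [train_table[i] for i in ids]
    classes = tuple(c for c in DEFAULT_VOCABULARY if c in set(toks))
    model = _stage("fit", lambda: fit_mlc(feats, toks, priors=cfg.priors, classes=classes))

    def _classify():
        if cfg.classifier == "mlc":
            labels, _ = classify_segments(model, segmap.spectral_modes)
            return labels
        return classify_baseline(cfg.classifier, model, segmap.spectral_modes)

    seg_labels = _stage("classification", _classify)

    def _detect():
        mask = vegetation_mask(segmap, seg_labels)
        comps = connected_components(mask, raster.transform)
        groups = partition_rows(comps, cfg.row_pitch, cfg.row_y_origin)
        pts, _ = run_parallel(groups, cfg.worker_count, d=cfg.d, seed=cfg.seed)
        return pts

    points = _stage("clustering", _detect)
    log[-1]["n_points"] = len(points)

    points = _stage(
        "indexing", lambda: index_all(points, segmap, seg_labels, HealthIndexParams(r=cfg.r))
    )
    ndvi_grid = _stage("ndvi", lambda: ndvi(raster))

    confusion = None
    report = None
    if reference_positions is not None:
        report = _stage(
            "validation",
            lambda: validate_run(points, reference_positions, reference_classes, cfg.effective_match_tol),
        )
        confusion = report["confusion"]

    if out_dir is not None:
        _stage("write", lambda: _write_artifacts(
            Path(out_dir), raster, segmap, seg_labels, points, ndvi_grid, confusion, cfg, log
        ))
    return PipelineResult(raster, segmap, model, seg_labels, points, ndvi_grid, confusion, report, log)


def validate_run(points, reference_positions, reference_classes, tol: float) -> dict:
    """Field-style validation: Table-shaped confusion over {EMPTY, 1..5},
    per-class precision, overall and within-one-level agreement."""
    det_xy = np.array([[p.x, p.y] for p in points], dtype=float).reshape(-1, 2)
    ref_xy = np.asarray(reference_positions, dtype=float).reshape(-1, 2)
    ref_cls = list(reference_classes)
    match = match_to_reference(det_xy, ref_xy, tol)
    det_of_ref = dict(match.pairs)
    classes = (NULL_CLASS, "1", "2", "3", "4", "5")
    truth_tokens, pred_tokens = [], []
    diffs = []
    for i, tcls in enumerate(ref_cls):
        t_empty = tcls in (None, NULL_CLASS)
        truth_tokens.append(NULL_CLASS if t_empty else str(int(str(tcls).replace("HL", ""))))
        j = det_of_ref.get(i)
        pc = points[j].health_class if j is not None else None
        pred_tokens.append(NULL_CLASS if pc is None else str(int(pc)))
        if not t_empty and pc is not None:
            diffs.append(abs(int(truth_tokens[-1]) - int(pc)))
    cm, precision = confusion_and_precision(truth_tokens, pred_tokens, classes)
    overall = float(np.diag(cm.counts).sum() / cm.total) if cm.total else float("nan")
    diffs = np.asarray(diffs)
    return {
        "confusion": cm,
        "precision": precision,
        "overall_agreement": overall,
        "matched": len(match.pairs),
        "spurious_detections": len(match.spurious_detections),
        "class_exact_rate": float((diffs == 0).mean()) if diffs.size else float("nan"),
        "class_within1_rate": float((diffs <= 1).mean()) if diffs.size else float("nan"),
    }


def health_counts_by_row(points: list[SeedingPoint]) -> pd.DataFrame:
    """Per-row counts of discrete health classes (field-report layout)."""
    rows = sorted({p.row_id for p in points})
    classes = [NULL_CLASS, 1, 2, 3, 4, 5]
    table = pd.DataFrame(0, index=[str(c) for c in classes], columns=[f"R{r + 1}" for r in range(len(rows))])
    colmap = {r: f"R{i + 1}" for i, r in enumerate(rows)}
    for p in points:
        cls = NULL_CLASS if p.health_class is None else p.health_class
        table.loc[str(cls), colmap[p.row_id]] += 1
    table["Sum"] = table.sum(axis=1)
    return table


def _write_artifacts(out, raster, segmap, seg_labels, points, ndvi_grid, confusion, cfg, log):
    out.mkdir(parents=True, exist_ok=True)
    layer = segmap.to_vector_layer(raster.band_names)
    write_vector(layer, out / "segments.geojson", allow_empty=True)
    for (geom, attrs), lab in zip(layer.features, seg_labels):
        attrs["class"] = lab
    write_vector(layer, out / "classified.geojson", allow_empty=True)
    write_vector(points_to_vector_layer(points, raster.crs_id), out / "seeding_points.geojson",
                 allow_empty=True)
    nd_mask = ~np.isfinite(ndvi_grid)
    nd = MultispectralRaster(("NDVI",), np.where(nd_mask, 0.0, ndvi_grid)[None],
                             raster.transform, raster.crs_id, nd_mask)
    write_raster(nd, out / "ndvi.tif")
    write_label_raster(segmap.label_grid, raster.transform, out / "segment_labels.tif", raster.crs_id)
    health_counts_by_row(points).to_csv(out / "counts_by_row.csv", index_label="I(p)")
    if confusion is not None:
        confusion.to_csv(out / "confusion.csv")
    run_log = {
        "version": __version__,
        "config": {
            "segmentation": asdict(cfg.segmentation),
            "classifier": cfg.classifier,
            "priors": cfg.priors,
            "d": cfg.d,
            "r": cfg.r,
            "row_pitch": cfg.row_pitch,
            "tile": cfg.tile,
            "margin": cfg.margin,
            "seed": cfg.seed,
            "worker_count": cfg.worker_count,
        },
        "stages": log,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)


# ---------------------------------------------------------------------------
# Segment-map persistence (CLI handoff between verbs)
# ---------------------------------------------------------------------------


def save_segment_map(segmap: SegmentMap, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_label_raster(segmap.label_grid, segmap.transform, d / "segment_labels.tif", segmap.crs_id)
    np.savez(
        d / "segment_data.npz",
        spatial_modes=segmap.spatial_modes,
        spectral_modes=segmap.spectral_modes,
        pixel_counts=segmap.pixel_counts,
    )


def load_segment_map(directory) -> SegmentMap:
    from .raster import read_label_raster

    d = Path(directory)
    labels, gt = read_label_raster(d / "segment_labels.tif")
    data = np.load(d / "segment_data.npz")
    return SegmentMap(labels, data["spatial_modes"], data["spectral_modes"],
                      data["pixel_counts"], gt)
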