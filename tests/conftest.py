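import numpy as np
import pytest

from cropgeobia import (
    GeoTransform,
    MultispectralRaster,
    PipelineConfig,
    SceneConfig,
    classify_segments,
    fit_mlc,
    generate_scene,
    run_pipeline,
    segment_tiled,
)
from cropgeobia.segmentation import SegmentMap
from cropgeobia.synth import truth_segment_labels

DEFAULT_SCENE_SEED = 0


def make_raster(values, pixel_size=1.0, origin=(0.0, None), bands=None, nodata=None):
    """Small-raster helper: values (B,H,W) with a simple metric transform."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[None]
    bands = bands or tuple(f"b{i}" for i in range(values.shape[0]))
    oy = origin[1] if origin[1] is not None else values.shape[1] * pixel_size
    gt = GeoTransform(origin[0], oy, pixel_size, pixel_size)
    return MultispectralRaster(tuple(bands), values, gt, "local", nodata)


def segmap_from_label_grid(label_grid, transform, spectral_modes=None):
    """Build a SegmentMap directly from a label grid (for geometry tests)."""
    label_grid = np.asarray(label_grid, dtype=np.int32)
    n = int(label_grid.max()) + 1
    counts = np.bincount(label_grid[label_grid >= 0], minlength=n)
    if spectral_modes is None:
        spectral_modes = np.zeros((n, 4))
    sp = np.zeros((n, 2))
    for lbl in range(n):
        rr, cc = np.nonzero(label_grid == lbl)
        sp[lbl] = (cc.mean(), rr.mean())
    return SegmentMap(label_grid, sp, np.asarray(spectral_modes, float), counts, transform)


@pytest.fixture(scope="session")
def default_scene():
    """The standard study-condition scene: 10 rows x 30 points, 2% noise."""
    return generate_scene(SceneConfig(seed=DEFAULT_SCENE_SEED))


@pytest.fixture(scope="session")
def default_run(default_scene):
    """Full pipeline output on the standard scene, shared across tests."""
    scene = default_scene
    segmap = segment_tiled(scene.raster)
    labels_true = truth_segment_labels(scene, segmap)
    result = run_pipeline(
        scene.raster,
        list(labels_true),
        PipelineConfig(seed=DEFAULT_SCENE_SEED),
        reference_positions=scene.truth_positions(include_empty=True),
        reference_classes=[c for _, _, c in scene.truth_points],
    )
    return {"scene": scene, "segmap": segmap, "labels_true": labels_true, "result": result}


@pytest.fixture(scope="session")
def small_scene():
    """A single double row of 12 points: quick end-to-end exercises."""
    return generate_scene(SceneConfig(rows=2, points_per_row=12, seed=3))
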