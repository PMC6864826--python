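"""Synthetic row-crop scene generator with full ground truth.

Emulates the layout of a pepper (Capsicum annuum) parcel: seeding points at
spacing d = 0.3 m along double rows with 0.5 m internal and 1.5 m external
separation, roughly circular plant canopies on a soil background, a thin
shadow fringe at plant edges, and 4-band (G, R, RE, NIR) reflectance-like
values where health classes separate mainly in the red-edge and NIR bands.
About half of the seeding points hold no surviving plant (the field
distribution observed on the reference parcel), marked with the EMPTY class.

All randomness flows from one integer seed; identical configurations produce
bit-identical scenes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .classification import ConfusionMatrix, confusion_and_precision
from .errors import ConfigurationError
from .indexing import NULL_CLASS, match_to_reference
from .raster import DEFAULT_BANDS, GeoTransform, MultispectralRaster
from .segmentation import SegmentMap

#: Class -> (G, R, RE, NIR) band means on a reflectance-percent scale.
#: Soil is bright and spectrally flat-ish; Shadow is dark everywhere;
#: the five health classes share similar visible bands and spread out in
#: RE and NIR, ordered from stressed (HL1) to vigorous (HL5).
DEFAULT_BAND_MEANS: dict[str, tuple[float, float, float, float]] = {
    "Soil": (18.0, 22.0, 26.0, 30.0),
    "Shadow": (4.0, 4.0, 6.0, 8.0),
    "HL1": (10.0, 9.0, 30.0, 42.0),
    "HL2": (10.5, 8.5, 36.0, 49.0),
    "HL3": (11.0, 8.0, 42.0, 56.0),
    "HL4": (11.5, 7.5, 48.0, 63.0),
    "HL5": (12.0, 7.0, 54.0, 70.0),
}

#: Canopy radius (mean, sd) in meters per health class: healthier plants are
#: larger; the healthiest approach half the seeding distance.
DEFAULT_RADII: dict[str, tuple[float, float]] = {
    "HL1": (0.115, 0.005),
    "HL2": (0.125, 0.005),
    "HL3": (0.135, 0.005),
    "HL4": (0.145, 0.005),
    "HL5": (0.150, 0.005),
}

#: Seeding-point class mix, including points where no plant survived; follows
#: the per-class proportions of the reference parcel's field counts.
DEFAULT_CLASS_MIX: dict[str, float] = {
    NULL_CLASS: 0.51,
    "HL1": 0.075,
    "HL2": 0.06,
    "HL3": 0.185,
    "HL4": 0.105,
    "HL5": 0.065,
}

TRUTH_CODES: dict[str, int] = {"Soil": 0, "Shadow": 1, "HL1": 2, "HL2": 3, "HL3": 4, "HL4": 5, "HL5": 6}
CODE_TO_TOKEN: dict[int, str] = {v: k for k, v in TRUTH_CODES.items()}


def default_noise_sd(band_means: dict | None = None, fraction: float = 0.02) -> np.ndarray:
    """Per-band noise sd as a fraction of the spread of the class means."""
    means = np.array(list((band_means or DEFAULT_BAND_MEANS).values()))
    return fraction * (means.max(axis=0) - means.min(axis=0))


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, spectra and noise of a synthetic scene.

    ``rows`` counts seeded lines (paired into double rows); ``d`` is the
    along-row seeding distance in meters; ``noise_sd`` is the per-band
    additive Gaussian sd (default: 2% of the per-band class-mean spread).
    """

    rows: int = 10
    points_per_row: int = 30
    d: float = 0.3
    double_row_gap: float = 0.5
    inter_row_gap: float = 1.5
    pixel_size: float = 0.04
    margin: float = 0.6
    plant_radius_by_class: dict = field(default_factory=lambda: dict(DEFAULT_RADII))
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    band_means: dict = field(default_factory=lambda: dict(DEFAULT_BAND_MEANS))
    noise_sd: tuple | None = None
    shadow_fringe_px: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_mix probabilities must sum to 1")
        if self.pixel_size <= 0 or self.d <= 0:
            raise ConfigurationError("pixel_size and d must be positive")
        if any(m <= 0 for m, _ in self.plant_radius_by_class.values()):
            raise ConfigurationError("plant radii must be positive")
        max_r = max(m + 3 * s for m, s in self.plant_radius_by_class.values())
        if 2 * max_r >= self.double_row_gap + self.d:
            raise ConfigurationError("plant radii too large for the declared row gaps")

    @property
    def effective_noise_sd(self) -> np.ndarray:
        if self.noise_sd is not None:
            return np.asarray(self.noise_sd, dtype=float)
        return default_noise_sd(self.band_means)

    def row_y_positions(self, height: float) -> list[float]:
        """World y of each seeded line, top line first."""
        ys = []
        for j in range(self.rows):
            pair, within = divmod(j, 2)
            offset = pair * (self.double_row_gap + self.inter_row_gap) + within * self.double_row_gap
            ys.append(height - self.margin - offset)
        return ys


@dataclass
class SyntheticSceneTruth:
    """Generated raster plus complete ground truth."""

    raster: MultispectralRaster
    truth_points: list[tuple[float, float, str]]  # (x, y, class token or EMPTY)
    truth_pixel_labels: np.ndarray  # int codes per TRUTH_CODES
    config: SceneConfig

    def truth_positions(self, include_empty: bool = True) -> np.ndarray:
        pts = [
            (x, y)
            for x, y, c in self.truth_points
            if include_empty or c != NULL_CLASS
        ]
        return np.asarray(pts, dtype=float).reshape(-1, 2)

    def plant_positions(self) -> np.ndarray:
        return self.truth_positions(include_empty=False)

    def plant_classes(self) -> list[int]:
        return [int(c[2:]) for _, _, c in self.truth_points if c != NULL_CLASS]


def generate_scene(cfg: SceneConfig | None = None) -> SyntheticSceneTruth:
    """Render a synthetic scene with per-pixel and per-point ground truth."""
    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    width = 2 * cfg.margin + (cfg.points_per_row - 1) * cfg.d
    n_pairs = (cfg.rows + 1) // 2
    extent = (n_pairs - 1) * (cfg.double_row_gap + cfg.inter_row_gap)
    if cfg.rows > 1:
        extent += cfg.double_row_gap if cfg.rows % 2 == 0 else 0.0
    height = 2 * cfg.margin + extent
    W = int(math.ceil(width / cfg.pixel_size))
    H = int(math.ceil(height / cfg.pixel_size))
    gt = GeoTransform(0.0, height, cfg.pixel_size, cfg.pixel_size)

    # draw the per-point classes and radii first so the stream is layout-independent
    tokens = list(cfg.class_mix)
    probs = np.array([cfg.class_mix[t] for t in tokens])
    ys = cfg.row_y_positions(height)
    truth_points = []
    draws = []
    for y in ys:
        for m in range(cfg.points_per_row):
            x = cfg.margin + m * cfg.d
            token = tokens[rng.choice(len(tokens), p=probs)]
            radius = 0.0
            if token != NULL_CLASS:
                mu, sd = cfg.plant_radius_by_class[token]
                radius = max(0.05, float(rng.normal(mu, sd)))
            truth_points.append((x, y, token))
            draws.append((x, y, token, radius))

    means = {k: np.asarray(v, dtype=float) for k, v in cfg.band_means.items()}
    values = np.empty((len(DEFAULT_BANDS), H, W))
    values[:] = means["Soil"][:, None, None]
    labels = np.full((H, W), TRUTH_CODES["Soil"], dtype=np.int16)

    cols = np.arange(W)
    rows_idx = np.arange(H)
    px, py = gt.pixel_to_world(cols, rows_idx)  # px: centers x, py: centers y
    fringe = cfg.shadow_fringe_px * cfg.pixel_size
    for x, y, token, radius in draws:
        if token == NULL_CLASS:
            continue
        r_out = radius + fringe
        c0 = max(0, int(np.searchsorted(px, x - r_out)) - 1)
        c1 = min(W, int(np.searchsorted(px, x + r_out)) + 1)
        # world y decreases with row index
        r0 = max(0, int(np.searchsorted(-py, -(y + r_out))) - 1)
        r1 = min(H, int(np.searchsorted(-py, -(y - r_out))) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        dx = px[c0:c1][None, :] - x
        dy = py[r0:r1][:, None] - y
        dist = np.hypot(dx, dy)
        ring = (dist > radius) & (dist <= r_out)
        disc = dist <= radius
        sub_lab = labels[r0:r1, c0:c1]
        sub_val = values[:, r0:r1, c0:c1]
        ring &= sub_lab == TRUTH_CODES["Soil"]  # fringe never eats a neighbor's canopy
        sub_val[:, ring] = means["Shadow"][:, None]
        sub_lab[ring] = TRUTH_CODES["Shadow"]
        sub_val[:, disc] = means[token][:, None]
        sub_lab[disc] = TRUTH_CODES[token]

    sd = cfg.effective_noise_sd
    if (sd > 0).any():
        values += sd[:, None, None] * rng.standard_normal(values.shape)
        np.clip(values, 0.0, None, out=values)

    raster = MultispectralRaster(DEFAULT_BANDS, values, gt, crs_id="local-metric")
    return SyntheticSceneTruth(raster, truth_points, labels, cfg)


def truth_segment_labels(scene: SyntheticSceneTruth, segmap: SegmentMap) -> list[str]:
    """Majority ground-truth class token per segment (training/validation aid)."""
    lab = segmap.label_grid
    valid = lab >= 0
    seg = lab[valid]
    code = scene.truth_pixel_labels[valid].astype(np.int64)
    n = segmap.n_segments
    ncode = max(TRUTH_CODES.values()) + 1
    counts = np.zeros((n, ncode), dtype=np.int64)
    np.add.at(counts, (seg, code), 1)
    return [CODE_TO_TOKEN[int(c)] for c in counts.argmax(axis=1)]


def truth_confusion(
    scene: SyntheticSceneTruth,
    predicted_points: np.ndarray,
    predicted_classes,
    tol: float | None = None,
) -> ConfusionMatrix:
    """Field-style validation matrix over {EMPTY, 1..5}.

    Detections are paired to truth seeding positions within ``tol`` (default
    d/2); an unmatched truth position counts as a predicted EMPTY, and a truth
    EMPTY point with no detection nearby is a correct EMPTY prediction.
    Spurious detections (no truth position within tol) have no truth row and
    are excluded from the matrix.
    """
    cfg = scene.config
    tol = cfg.d / 2 if tol is None else tol
    predicted_points = np.asarray(predicted_points, dtype=float).reshape(-1, 2)
    truth_xy = scene.truth_positions(include_empty=True)
    truth_cls = [c for _, _, c in scene.truth_points]
    match = match_to_reference(predicted_points, truth_xy, tol)
    classes = (NULL_CLASS, "1", "2", "3", "4", "5")
    truth_tokens = []
    pred_tokens = []
    det_of_ref = dict(match.pairs)
    for i, tcls in enumerate(truth_cls):
        truth_tokens.append(NULL_CLASS if tcls == NULL_CLASS else tcls[2:])
        if i in det_of_ref:
            pc = predicted_classes[det_of_ref[i]]
            pred_tokens.append(NULL_CLASS if pc is None else str(int(pc)))
        else:
            pred_tokens.append(NULL_CLASS)
    cm, _ = confusion_and_precision(truth_tokens, pred_tokens, classes)
    return cm
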