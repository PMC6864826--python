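"""Ground-truth utilities: spectrometer wavelength mapping, reflectance
calibration, signature-to-segment label transfer, and phenotype-based health
categorization.

The portable field spectrometer (Hamamatsu C12880MA, 288 channels) maps its
channel index x to a wavelength through a factory-fitted fifth-degree
polynomial p(x) = A0 + B1 x + ... + B5 x^5, rounded to the nearest nanometer.
Plant health categories HL1 (worst) .. HL5 (best) are defined by binned
phenotypic traits: plant height, canopy surface, and the percentages of
curly, spotted and chlorotic leaves.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.strtree import STRtree

from .errors import ValidationError
from .raster import GeoPointRecord
from .segmentation import SegmentMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WavelengthPolynomial:
    """Fifth-degree channel-to-wavelength map, valid for channels 0..287."""

    A0: float
    B1: float
    B2: float
    B3: float
    B4: float
    B5: float

    def __call__(self, x: float) -> float:
        return (
            self.A0
            + self.B1 * x
            + self.B2 * x**2
            + self.B3 * x**3
            + self.B4 * x**4
            + self.B5 * x**5
        )


#: Factory coefficients for the C12880MA unit SN17I00621.
C12880MA_SN17I00621 = WavelengthPolynomial(
    A0=3.17926058e2,
    B1=2.69726310,
    B2=-1.32864319e-3,
    B3=-5.39983110e-6,
    B4=-7.95625547e-10,
    B5=2.01449675e-11,
)


def wavelength_of_pixel(x: int, poly: WavelengthPolynomial = C12880MA_SN17I00621) -> int:
    """Wavelength in integer nm for sensor channel ``x`` (round-half-up)."""
    if not (0 <= x <= 287):
        raise ValidationError(f"channel index {x} outside the valid range [0, 287]")
    return int(np.floor(poly(float(x)) + 0.5))


def calibrate_reflectance(
    raw: np.ndarray, panel_reference: np.ndarray, light_level: float = 1.0
) -> np.ndarray:
    """Linear reflectance calibration against a reference panel.

    reflectance = (raw / light_level) / panel_reference, clipped to [0, 1.5].
    This is an explicit, documented linear contract; channels with a zero
    panel reference are masked to NaN with a warning.
    """
    raw = np.asarray(raw, dtype=float)
    panel = np.asarray(panel_reference, dtype=float)
    if raw.shape != panel.shape:
        raise ValidationError("raw and panel_reference must share one shape")
    if light_level <= 0:
        raise ValidationError("light_level must be positive")
    out = np.full(raw.shape, np.nan)
    ok = panel != 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero panel-reference channel(s) masked", stacklevel=2)
    out[ok] = np.clip((raw[ok] / light_level) / panel[ok], 0.0, 1.5)
    return out


def assign_labels(signatures: list[GeoPointRecord], segmap: SegmentMap) -> dict[int, str]:
    """Transfer point labels onto the segments containing them.

    Conflicting labels within one segment resolve by majority; exact ties
    leave the segment unlabeled with a warning.  Points falling outside every
    segment are reported via the logger; if none land inside, an empty table
    is returned with a warning.
    """
    footprints = segmap.footprints()
    tree = STRtree(footprints)
    votes: dict[int, Counter] = {}
    outside = 0
    for rec in signatures:
        pt = shapely.Point(rec.x, rec.y)
        hits = [int(i) for i in tree.query(pt, predicate="covered_by")]
        if not hits:
            outside += 1
            continue
        votes.setdefault(hits[0], Counter())[rec.label] += 1
    if outside:
        logger.warning("%d signature point(s) fell outside every segment", outside)
    if not votes:
        warnings.warn("no signature point landed inside any segment", stacklevel=2)
        return {}
    table: dict[int, str] = {}
    for sid, counter in votes.items():
        ranked = counter.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            warnings.warn(f"segment {sid} has tied labels {ranked[0][0]}/{ranked[1][0]}; left unlabeled",
                          stacklevel=2)
            continue
        table[sid] = ranked[0][0]
    return table


# ---------------------------------------------------------------------------
# Phenotype categorization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeRecord:
    """Observed traits of one plant."""

    height_cm: float
    surface_m2: float
    curly_pct: float
    spotted_pct: float
    chlorotic_pct: float

    def __post_init__(self) -> None:
        for name in ("curly_pct", "spotted_pct", "chlorotic_pct"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValidationError(f"{name}={v} outside [0, 100]")
        if self.height_cm < 0 or self.surface_m2 < 0:
            raise ValidationError("height and surface must be non-negative")


# Trait bins, category edges from worst (1) to best (5).  Lower bounds are
# inclusive, upper bounds exclusive ("30 to <40" style); the inclusive-upper
# printed bins (height 50-60, surface 0.20-0.25) close at the top, and the
# worst symptom bin closes at its lower edge so binning is total.
def _level_height(v: float) -> int:
    if v < 30:
        return 1
    if v < 40:
        return 2
    if v < 50:
        return 3
    if v <= 60:
        return 4
    return 5


def _level_surface(v: float) -> int:
    if v < 0.10:
        return 1
    if v < 0.15:
        return 2
    if v < 0.20:
        return 3
    if v <= 0.25:
        return 4
    return 5


def _level_curly(v: float) -> int:
    if v >= 60:
        return 1
    if v >= 30:
        return 2
    if v >= 15:
        return 3
    if v >= 10:
        return 4
    return 5


def _level_spotted(v: float) -> int:
    if v >= 20:
        return 1
    if v >= 10:
        return 2
    if v > 0:
        return 3
    return 5  # 0% sits in both top columns; best consistent level


def _level_chlorotic(v: float) -> int:
    if v >= 40:
        return 1
    if v >= 20:
        return 2
    if v > 0:
        return 3
    return 5


_TRAIT_LEVELS = {
    "height_cm": _level_height,
    "surface_m2": _level_surface,
    "curly_pct": _level_curly,
    "spotted_pct": _level_spotted,
    "chlorotic_pct": _level_chlorotic,
}


def trait_levels(rec: PhenotypeRecord) -> dict[str, int]:
    """Per-trait health level 1..5 for each phenotypic trait."""
    return {name: fn(getattr(rec, name)) for name, fn in _TRAIT_LEVELS.items()}


def categorize_phenotype(rec: PhenotypeRecord, rule: str = "min") -> str:
    """Overall HL category from the per-trait levels.

    ``min`` (default): the worst trait decides -- a plant is as healthy as its
    weakest symptom allows.  ``majority``: the most frequent trait level, ties
    resolved toward the worse level.
    """
    levels = list(trait_levels(rec).values())
    if rule == "min":
        cat = min(levels)
    elif rule == "majority":
        counts = Counter(levels)
        best = max(counts.values())
        cat = min(l for l, c in counts.items() if c == best)
    else:
        raise ValidationError("rule must be 'min' or 'majority'")
    return f"HL{cat}"
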