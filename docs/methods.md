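# Methods

This note documents the models, parameter choices and numerical conventions
behind `cropgeobia`, and what the synthetic test scenes do and do not show
about real imagery.

## Mean-shift segmentation

Pixels live in the joint domain: two spatial coordinates (pixel units) plus
B spectral coordinates (band units). The mode estimate of pixel `i` starts at
the pixel itself and repeatedly moves to the kernel-weighted mean of the
pixels within spatial range `h_s` **and** spectral range `h_r` of the current
estimate. The kernel acts on the range-normalized joint difference
`u = (Δs/h_s, Δr/h_r)`; the default profile is Epanechnikov
`max(0, 1 − |u|²)` with a Gaussian `exp(−|u|²/2)` alternative. Iteration
stops when the joint displacement (raw units, spatial + spectral combined)
falls below `conv_threshold` or after `max_iter` steps.

Parameters and defaults:

| name | default | units | role |
|---|---|---|---|
| `h_s` | 5 | px | spatial kernel range; plant-organ scale at ~4 cm/px |
| `h_r` | 15 | band units | spectral kernel range |
| `max_iter` | 100 | – | iteration cap |
| `conv_threshold` | 0.1 | joint units | convergence displacement |
| `merge_tol` | `h_r/2` | band units | modes closer than this are "the same mode" |
| `min_segment_size` | 4 | px | speckle suppression |

`h_s` and `h_r` are the field-standard values for this application; the
remaining knobs follow common large-scale mean-shift tooling conventions and
are exposed in `MeanShiftParams`. `h_r` is interpreted in raw band units —
the pipeline is agnostic about whether the raster holds radiance, DN or
reflectance-percent values, so the user owns the scaling.

Segment formation: 4-connected pixels whose converged spectral modes differ
by at most `merge_tol` (Euclidean over bands) join one segment (connected
components of the thresholded adjacency graph, labels dense in scan order of
first occurrence). Segments below `min_segment_size` merge into the adjacent
segment with the nearest spectral mode, ties toward the lower label. Each
segment carries its mean spatial and spectral mode and a polygonal footprint
(union of pixel cells, world coordinates), built lazily.

Tiled execution processes the raster in tiles with an overlap margin of
`min(ceil(2 h_s √max_iter), tile/2)` — a bound on how far spatial modes can
travel — keeping core-region modes identical to the untiled run, then merges
modes globally, which also unifies segments crossing tile borders. A raster
smaller than one tile takes the untiled path exactly.

**Numerical notes.** With the Epanechnikov profile the joint squared distance
can reach 2 inside the window (both ranges at their limit), where the profile
is clamped at 0 — such pixels satisfy the range test but carry no weight.
If every candidate neighbor has zero weight the iteration stops in place.
Refiltering a filtered image is exactly stable on separated piecewise-constant
input; on noisy input the residual drift is of the order of the within-cluster
mode spread (not the convergence threshold), because the second pass sees the
filtered values as new data. The tests cover both regimes.

## Maximum-likelihood classification

Features are exactly the segments' 4-band spectral modes; per-pixel
classification is deliberately out of scope. Training computes per-class
sample means and maximum-likelihood (1/n) covariances. When a covariance is
near-singular (smallest eigenvalue < 1e-10·trace — e.g. noiseless synthetic
classes), a ridge `1e-6·trace(Σ)/dim · I` restores positive definiteness.
Priors are uniform by default (empirical selectable); with four-band features
and well-separated classes the choice is immaterial, and uniform keeps the
decision rule interpretable as a pure density comparison. Log-domain
evaluation (Cholesky + log-sum-exp) keeps posteriors normalized to 1e-9 even
for far-out feature vectors. Exact posterior ties resolve to the first class
in declared order.

Per-class **precision** is reported as the diagonal count divided by its
truth-row total — the statistic that matches published per-class columns for
this kind of validation table. The textbook-looking alternative TP/(TP+TN)
is also exposed (`ConfusionMatrix.precision("tp_tn")`) but is not the default,
since it does not reproduce such columns.

## Seeding-point detection

Vegetation = segments classified HL1…HL5; Soil and Shadow are excluded. The
binary vegetation mask is split into 4-connected components (4-connectivity
everywhere, matching the segmentation convention). For a component of area
`a` (pixel count × pixel area), the expected number of plants is the number
of inscribed circles of diameter `d`: `k = 4a/(πd²)`, rounded half-up with a
floor of 1. `d` defaults to 0.3 m, the along-row seeding distance of the
emulated layout.

KMeans runs on the component's pixel **world coordinates only** (spectral
data deliberately discarded), via scikit-learn's Lloyd algorithm: k-means++
initialization from a deterministic seed, at most 20 iterations, empty
clusters relocated to the farthest points. Each component's seed is derived
from the base seed and the component id, so a run partitioned by plowing row
merges to exactly the serial result — the testable form of the
no-data-dependency claim that licenses parallel execution. Components of
fewer than 3 pixels yield a single point at their centroid. No post-hoc
center merging is performed.

Row partitioning defaults to banding on the world y coordinate with a
configured pitch (row id = nearest band); explicit row polygons override
banding, and a component straddling rows is assigned by its centroid.

## Health index

`I(p)` averages the integer health levels of the segments whose footprints
intersect the closed disc `B(p, r)`, `r` = 0.075 m by default (half the
0.15 m canopy radius of a healthy plant; smaller than d/2 so neighboring
plants rarely intrude). Intersection uses exact polygon–disc geometry
(shapely, boundary contact counts; the disc is a 256-gon buffer, radius
error < 1e-4 relative). Soil/Shadow members of the disc set carry no health
level and are excluded from the average by default, keeping `I(p)` within
[1, 5]; `include_nonvegetation=True` counts them as zeros for sensitivity
analyses. If no qualifying segment intersects the disc the point reports the
empty marker. For map and table output `I(p)` is discretized round-half-up
to a class 1–5.

Validation mirrors a field survey: detections pair greedily (globally
nearest first) with the expected seeding grid within `d/2`; unmatched grid
positions count as predicted-empty, unmatched detections as spurious. The
confusion matrix runs over {EMPTY, 1…5}.

## Phenotype categories and field utilities

Health categories HL1 (worst) … HL5 (best) bin five phenotypic traits:
height (cm), canopy surface (m²), and percentages of curly, spotted and
chlorotic leaves. Bins are lower-inclusive / upper-exclusive ("30 to <40");
the printed-style inclusive bins (height 50–60, surface 0.20–0.25) close at
the top, and the worst symptom bin closes at its lower edge so that binning
is total. A spotted/chlorotic percentage of exactly 0 is consistent with the
two best columns and maps to the best level. A plant's category is the
minimum of its per-trait levels — the worst symptom decides — with a
majority-vote alternative; the min rule makes the category monotone in every
trait, which the tests assert.

The 288-channel spectrometer's channel→wavelength map is the factory
fifth-degree polynomial with the published coefficients for unit SN17I00621,
rounded half-up to integer nm (channel 0 → 318 nm; strictly increasing to
889 nm at channel 287). Reflectance calibration is an explicit linear
contract — `(raw/light_level)/panel`, clipped to [0, 1.5], zero-panel
channels masked — standing in for unpublished device firmware; signatures
are used to carry labels and positions, not as classifier features.

## Synthetic scenes

The generator emulates the study layout: seeded lines paired into double
rows (0.5 m internal, 1.5 m external separation), 30 points per line at
d = 0.3 m, 0.04 m pixels. Each seeding point draws a class from
{EMPTY, HL1…HL5} with probabilities following the field distribution of the
emulated parcel (≈51% empty); surviving plants are discs with
class-dependent radius (0.115 m for HL1 up to 0.150 m for HL5, sd 5 mm —
healthier plants are larger, the healthiest approaching d/2 so that
neighbors can touch and exercise the k > 1 clustering path). A 1-px shadow
ring surrounds each canopy (drawn only over soil, so canopies keep
priority), matching the use of Shadow as a catch-all low-reflectance class.

Band means are on a reflectance-percent scale chosen so that the standard
`h_r = 15` is meaningful: soil bright and flat-ish (NIR 30), shadow dark
(NIR 8), and the five health classes nearly identical in G/R but spread in
RE (30→54) and NIR (42→70) — the bands that carry health signal in this
domain. Additive Gaussian noise defaults to 2% of the per-band spread of
the class means (≈1.2 units in NIR), clipped at zero. All randomness flows
from one integer seed; identical configurations are bit-identical.

**What passing tests show — and don't.** The scenes exercise every operator
(mode-seeking, merge, area→k, Voronoi splitting, disc intersection,
matching) under the declared geometry and noise, and the irregular-shape
path via touching discs. They do not model BRDF, terrain, mixed pixels at
4 cm resolution, canopy texture, or class overlap in feature space; real
imagery will yield lower classification accuracy than the near-perfect
synthetic numbers, with errors concentrated between adjacent health levels.

## Problem sizes and determinism

The standard test scene is 10 rows × 30 points (~300 seeding points,
~60k pixels), which the full pipeline processes in a few seconds thanks to
the compiled mean-shift core; unit tests use ≤ 64×64 rasters so that
brute-force oracles stay exact and fast. Pipeline runs under a fixed seed
are byte-identical, including vector artifacts on disk.

## Known limitations

- The method presumes a known, uniform seeding distance and roughly
  plant-sized segments; irregular planting breaks the k = 4a/(πd²) rule.
- Greedy matching is not a globally optimal assignment; on sub-tolerance
  jitter they coincide (tested), but adversarial layouts can differ.
- The tiled path guarantees identical modes only when mode trajectories stay
  within the overlap margin; pathological flat-density rasters could exceed
  it.
- `h_r` is scale-dependent; rasters in 14-bit DN units need a rescaled `h_r`
  (or rescaled data) to match the defaults' behavior.
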