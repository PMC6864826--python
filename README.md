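# cropgeobia

Object-based plant-health mapping for row-crop multispectral orthomosaics.

Very-high-resolution UAV imagery of a row crop (here: *Capsicum annuum* style
layouts) carries more information than a per-pixel vegetation index can
express. `cropgeobia` implements a GEOBIA (geographic object-based image
analysis) pipeline that turns a 4-band (G 550 / R 660 / RE 735 / NIR 790 nm)
orthomosaic into a **per-seeding-point health map**: one discrete health grade
for every position where a plant was sown, including the positions where no
plant survived. It is aimed at precision-agriculture researchers and
agronomists who want plant-level condition maps rather than NDVI rasters.

## Method

1. **Segmentation.** Joint spatial–spectral mean shift: each pixel
   `x_i = (x_i^s, x_i^r)` iterates
   `y_{i,j+1} = Σ_{x_k∈N(y_{i,j})} K(x_k − y_{i,j}) x_k / Σ K(x_k − y_{i,j})`
   toward its density mode, with `N(y)` the pixels within spatial range `h_s`
   (5 px) and spectral range `h_r` (15 band units) and `K` an Epanechnikov
   kernel. Adjacent pixels converging to the same mode form a segment; a tiled
   execution mode handles large rasters.
2. **Classification.** Segments — not pixels — are classified by Gaussian
   maximum likelihood on their 4-band spectral modes ω into
   {Soil, Shadow, HL1…HL5}, where HL1…HL5 are health levels from worst to
   best: `C(ω) = argmax_C P(ω|C) P(C)` with `P(ω|C) = N(μ_C, Σ_C)`.
   Minimum-distance-to-means and spectral-angle-mapper baselines are included.
3. **Plant detection.** Vegetation pixels (HL segments) → 4-connected
   components; a component of area `a` holds `k = 4a/(πd²)` plants for seeding
   distance `d` (0.3 m); Lloyd's KMeans (≤ 20 iterations) on the component's
   pixel coordinates places the `k` seeding points.
4. **Health index.** `I(p) = (1/n) Σ_{s∈S_{p,r}} I(s)` averages the health
   levels of the segments intersecting the disc `B(p, r)` (r = 7.5 cm), then
   discretizes to a 1–5 grade. NDVI `(NIR−R)/(NIR+R)` is provided for
   comparison.
5. **Evaluation & performance.** Confusion matrices with per-class precision;
   per-plowing-row partitioning makes detection embarrassingly parallel, with
   Amdahl's-law accounting `S(N_p) = 1/((1−P) + P/N_p)`.

A synthetic scene generator reproduces the study layout (double rows, 0.3 m
spacing, class-dependent canopy sizes, shadow fringes, RE/NIR-separated class
spectra, ~51% empty points) with full ground truth, so the whole pipeline is
testable without field data. See `docs/methods.md` for modeling details.

## Worked example

```python
from cropgeobia import (PipelineConfig, SceneConfig, generate_scene,
                        run_pipeline, segment_tiled)
from cropgeobia.synth import truth_segment_labels

scene = generate_scene(SceneConfig(seed=1))          # 10 rows x 30 points
segmap = segment_tiled(scene.raster)                 # 443 segments
labels = truth_segment_labels(scene, segmap)         # training labels
result = run_pipeline(
    scene.raster, list(labels), PipelineConfig(seed=1),
    reference_positions=scene.truth_positions(include_empty=True),
    reference_classes=[c for _, _, c in scene.truth_points],
)
print(len(result.points), result.report["overall_agreement"])
```

prints `146 1.0`: all 146 surviving plants are found within d/2 of their true
seeding points and every one receives its true health grade (the validation
confusion matrix is diagonal). On this scene the NDVI map only separates
vegetation (≈ 0.75) from soil (≈ 0.16); the pipeline's extra output is the
five-level health grading of each plant. The scripts in `examples/` walk
through each capability (scene simulation, segmentation + classification,
detection + indexing, validation, speedup accounting) and print these numbers
with commentary; a thin CLI (`cropgeobia simulate|segment|train|classify|
detect|index|validate|run-all`) mirrors the same stages for shell use.

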