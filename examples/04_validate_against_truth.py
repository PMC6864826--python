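"""Field-style validation: confusion matrix and per-class precision.

Compares pipeline output against the generator's ground truth the same way a
field survey would — matching detections to the expected seeding grid within
d/2 and tabulating truth vs predicted health classes, including the no-plant
(EMPTY) class.
"""

import numpy as np

from cropgeobia import PipelineConfig, SceneConfig, generate_scene, run_pipeline, segment_tiled
from cropgeobia.synth import truth_segment_labels

scene = generate_scene(SceneConfig(seed=1))
segmap = segment_tiled(scene.raster)
labels = truth_segment_labels(scene, segmap)

result = run_pipeline(
    scene.raster, list(labels), PipelineConfig(seed=1),
    reference_positions=scene.truth_positions(include_empty=True),
    reference_classes=[c for _, _, c in scene.truth_points],
)

report = result.report
print("confusion matrix (rows = truth, columns = predicted):")
print(result.confusion.to_dataframe())
print("per-class precision:", np.round(report["precision"], 4))
print(f"overall agreement:  {report['overall_agreement']:.4f}")
print(f"exact health class: {report['class_exact_rate']:.4f}")
print(f"within one level:   {report['class_within1_rate']:.4f}")
# Off-diagonal mass, when it appears, sits next to the diagonal: errors
# confuse adjacent health levels, not healthy with dead plants.
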