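"""Generate a phantom valve, preprocess it, and score a perturbed copy.

Walks the non-learning half of the pipeline: synthetic case generation, the
valve coordinate frame, the spacing rule, ROI resampling, and the DSC/MBD
metrics.  The "prediction" here is the ground truth eroded by one voxel, a
stand-in for a slightly undersized segmentation.
"""

import numpy as np
import scipy.ndimage as ndi

from leafletseg.core import LeafletLabelMap
from leafletseg.evaluation import evaluate_case
from leafletseg.phantom import make_phantom
from leafletseg.preprocess import (
    ResamplePlan,
    build_valve_frame,
    choose_spacing,
    measure_leaflet_heights,
    resample_case,
)

case = make_phantom(seed=7)
print(f"phantom: {case.sequence.n_frames} frames on a {case.gt.grid.shape} grid "
      f"at {case.gt.grid.spacing[0]} mm")

frame = build_valve_frame(case.annotation)
heights = measure_leaflet_heights(case.gt, frame)
spacing = choose_spacing(case.gt, frame)
print("leaflet extents along the valve axis (mm):",
      {k: round(v, 2) for k, v in heights.items()})
print(f"rule-selected spacing: {spacing} mm  (min of the 0.25 mm cap and h/6)")

plan = ResamplePlan(spacing_mm=0.55, transform=frame, roi_shape=(48, 48, 48))
_, gt, _ = resample_case(case.sequence, case.gt, case.annotation, plan)

eroded = np.zeros_like(gt.labels)
for label in (1, 2, 3):
    eroded[ndi.binary_erosion(gt.labels == label)] = label
pred = LeafletLabelMap(labels=eroded, grid=gt.grid)

row = evaluate_case(pred, gt)
for name in ("anterior", "posterior", "septal", "average", "merged"):
    print(f"  {name:9s}  DSC {row['dsc_' + name]:.3f}   MBD {row['mbd_' + name]:.3f} mm")
print("Eroding by one voxel costs roughly one voxel of boundary distance;"
      " thin structures lose DSC quickly, which is why the spacing rule"
      " guarantees 6 voxels across the thinnest leaflet.")
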