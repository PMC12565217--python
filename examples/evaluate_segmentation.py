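"""Segmentation metrics between a reference mask volume and a perturbed
prediction.

Builds a 4-slice phantom volume, erodes/shifts the masks to mimic an
imperfect segmenter, and prints the per-class overlap and boundary
metrics a stroke-segmentation study reports: Dice/IoU in 2-D and 3-D,
HD95 and ASSD in millimetres (0.5 x 0.5 x 5 mm voxels), and the trimap
F-measure in a 5-pixel boundary band.
"""

import numpy as np
from scipy import ndimage

from ctprep import MaskVolume, generate_phantom, metric_report

slices = [generate_phantom(seed=s, size=128) for s in range(4)]
true = MaskVolume(np.concatenate([s.masks.core for s in slices]),
                  np.concatenate([s.masks.penumbra for s in slices]))

pred_core = np.stack([ndimage.binary_erosion(m) for m in true.core])
pred_pen = np.stack([np.roll(m, 2, axis=1) for m in true.penumbra])
pred = MaskVolume(pred_core, pred_pen & ~pred_core)

rep = metric_report(pred, true)
for cls in ("core", "penumbra"):
    print(f"{cls:9s} Dice3D={rep.dice3d[cls]:.3f} IoU3D={rep.iou3d[cls]:.3f} "
          f"HD95={rep.hd95[cls]:.2f}mm ASSD={rep.assd[cls]:.2f}mm "
          f"trimapF={rep.trimap_f[cls]:.3f}")
print("erosion costs a little overlap everywhere; the 2-px shift of the")
print("penumbra shows up most strongly in the boundary-sensitive metrics.")
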