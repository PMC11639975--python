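"""Evaluate the training losses and detection/segmentation metrics.

Prints the dual segmentation loss (cross-entropy + Dice), the smooth-L1
box regression penalty, the focal classification loss, and the
detection-evaluation outputs (single-class precision at an IoU threshold,
plus the ranked all-point AP) on small hand-built inputs.
"""

import numpy as np

from exactnet.imgio import Box3D
from exactnet.objectives import (
    FocalParams,
    average_precision,
    dice_loss,
    dsc,
    dual_seg_loss,
    focal_loss,
    iou3d,
    smooth_l1,
)

# dual segmentation loss: perfect, half-overlap, disjoint
y = np.zeros((2, 8, 8, 8))
y[1, 2:6, 2:6, 2:6] = 1
y[0] = 1 - y[1]
print("dual loss, perfect prediction:", round(dual_seg_loss(y, y), 6))

p_half = np.zeros((8, 8, 8))
t_half = np.zeros((8, 8, 8))
p_half[0:4, 0, 0] = 1
t_half[2:6, 0, 0] = 1
print("Dice loss at half overlap:", dice_loss(p_half, t_half))  # 0.5

# smooth-L1 on the mean absolute box-coordinate error (delta = 1)
a = [Box3D((0, 0, 0), (4, 4, 4))]
b = [Box3D((3, 3, 3), (7, 7, 7))]  # every coordinate off by 3 -> MAE 3
print("smooth-L1 at MAE 3:", smooth_l1(a, b))  # 3 - 0.5 = 2.5

# focal loss: a hard positive at p = 0.5 with canonical alpha/gamma
print("focal loss p=0.5, y=1:", round(focal_loss(0.5, 1.0, FocalParams(0.25, 2.0)), 5))

# masks and boxes
x1 = np.zeros((10, 10, 10), bool)
x2 = np.zeros((10, 10, 10), bool)
x1[:5] = True
x2[2:7] = True
print("DSC of 100-voxel masks sharing 60%:", round(dsc(x1, x2), 3))
print("IoU of shifted unit cubes:", round(iou3d(Box3D((0, 0, 0), (2, 2, 2)), Box3D((1, 1, 1), (3, 3, 3))), 4))

# detection evaluation: 3 correct predictions + 1 spurious
truth = [Box3D((i * 10, 0, 0), (i * 10 + 4, 4, 4)) for i in range(3)]
preds = [Box3D(t.lo, t.hi, score=0.9) for t in truth] + [Box3D((0, 20, 20), (4, 24, 24), score=0.6)]
ev, precision, ap = average_precision(preds, truth, iou_threshold=0.5)
print(f"detection: TP={ev.tp} FP={ev.fp} FN={ev.fn} precision={precision:.2f} ranked AP={ap:.2f}")
# precision 0.75: three of four predictions hit a distinct truth box.
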