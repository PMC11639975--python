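"""Train tiny networks and run the full two-stage pipeline (several minutes).

Trains a desk-scale UNet3D nodule segmenter and Retina-UNet3D detector on a
small phantom cohort, then runs detection -> lobe assignment -> EHR-guided
filtering -> candidate segmentation on a held-out phantom and reports what
each stage produced.  Sizes are kept small so this runs in a few minutes on
one CPU; expect detection scores near 1 for true nodules.
"""

import numpy as np

from exactnet.experiment import make_phantom_cohort
from exactnet.imgio import clip_hu
from exactnet.nets import NetConfig, build_detector, build_segmenter
from exactnet.objectives import dsc
from exactnet.pipeline import (
    AugPolicy,
    TrainConfig,
    assign_lobe,
    ehr_guided_filter,
    lobe_contact_filter,
    segment_candidates,
    sliding_window_predict,
    train_model,
)
from exactnet.reports import extract_findings_rules

train_cohort = make_phantom_cohort(8, seed=11, grid_shape=(48, 48, 48))
test_case = make_phantom_cohort(1, seed=99, grid_shape=(48, 48, 48))[0]
cases = [c.case for c in train_cohort]

intensity_only = dict(noise_sd_max=0.02, blur_sigma_max=0.3, brightness=(-0.03, 0.03),
                      contrast=(0.97, 1.03), gamma=(0.95, 1.05))
net_cfg = dict(base_channels=4, depth=3, n_classes=2, patch_size=24, anchor_sizes_mm=(8.0,), seed=0)

print("training segmenter ...")
seg = build_segmenter(NetConfig(**net_cfg))
seg, seg_trace = train_model(
    seg, cases,
    TrainConfig(iterations=500, patch_size=24, lr=3e-3, foreground_fraction=0.8, seed=0),
    AugPolicy.segmentation(seed=0, rotation_deg=0, scale_range=(1.0, 1.0), flip_axes=(), **intensity_only),
)
print(f"  final loss {np.mean(seg_trace[-20:]):.3f}")

print("training detector ...")
det = build_detector(NetConfig(**net_cfg))
det, det_trace = train_model(
    det, cases,
    TrainConfig(iterations=400, patch_size=24, lr=2e-3, foreground_fraction=0.8, seed=0),
    AugPolicy.detection(seed=0, **intensity_only),
)
print(f"  final loss {np.mean(det_trace[-20:]):.3f}")

vol = clip_hu(test_case.case.volume)
boxes = sliding_window_predict(det, vol, patch_size=24, score_threshold=0.5, nms_iou=0.1)
print(f"\nstage 1: {len(boxes)} candidates (truth has {len(test_case.case.truth_boxes)} nodules)")

cands = lobe_contact_filter([assign_lobe(b, test_case.case.lobes) for b in boxes])
confirmed = extract_findings_rules(test_case.report_text)
print(f"confirmed lobe(s) from the report: {sorted(confirmed.lobes)}")
outcome = ehr_guided_filter(cands, confirmed)
print(f"guidance: {len(outcome.retained)} retained, {len(outcome.removed)} removed")
for c in outcome.removed:
    print(f"  removed {c.box.lo}->{c.box.hi} (lobe {c.lobe}, score {c.score:.2f})")

with_contours = segment_candidates(seg, vol, outcome.retained, crop_size=32)
pred = np.zeros(vol.shape, bool)
for c in with_contours:
    pred |= c.contour
tumor_mask = np.isin(test_case.case.nodule_mask.labels, [j + 1 for j in test_case.tumor_indices])
print(f"stage 2: nodule DSC vs phantom truth = {dsc(pred, tumor_mask):.3f}")
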