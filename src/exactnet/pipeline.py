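"""Training and two-stage inference workflow.

Stage one runs the detector over the whole (preprocessed) volume with a
sliding window and pools the candidates.  Each candidate box is assigned
the pulmonary lobe it overlaps most; candidates touching no lobe are
discarded (vessels, chest wall, scanner noise).  The EHR guidance signal —
the confirmed tumor lobe(s) parsed from clinical reports — then removes
candidates outside the confirmed lobes (``filter`` mode) or restricts the
volume to the confirmed lobes before re-detection (``mask`` mode).  Stage
two crops a fixed-size patch around every surviving candidate and runs the
nodule segmentation model to delineate its contour.

Training uses the sliding-patch scheme: fixed-size patches sampled from the
cases (half centered on foreground, half uniform), augmented per policy,
one optimizer step per patch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imgio import Box3D, LabelMap, Volume, normalize_hu
from .nets import Adam, DetectionModel, SegmentationModel, decode_detections, nms
from .phantom import HU_AIR, PhantomCase
from .reports import LOBE_CODES, ExtractionResult

__all__ = [
    "AugPolicy",
    "TrainConfig",
    "CandidateNodule",
    "GuidanceOutcome",
    "draw_aug_params",
    "augment_sample",
    "train_model",
    "sliding_window_predict",
    "assign_lobe",
    "lobe_contact_filter",
    "ehr_guided_filter",
    "segment_candidates",
]

LOBE_LABELS = {code: i + 1 for i, code in enumerate(LOBE_CODES)}
LABEL_TO_CODE = {v: k for k, v in LOBE_LABELS.items()}


@dataclass(frozen=True)
class AugPolicy:
    """Spatial + intensity augmentation ranges for one task.

    The segmentation policy rotates up to +/-30 degrees per axis, scales
    70-140%, and flips along each axis; the detection policy uses the same
    intensity augmentations but has rotation and flipping disabled (boxes
    are axis-aligned, and the detector's anchors assume the native axes).
    Intensity ranges act on window-normalised values in [0, 1].
    """

    task: str = "segmentation"
    rotation_deg: float = 30.0
    scale_range: tuple[float, float] = (0.7, 1.4)
    flip_axes: tuple[int, ...] = (0, 1, 2)
    noise_sd_max: float = 0.03
    blur_sigma_max: float = 0.8
    brightness: tuple[float, float] = (-0.1, 0.1)
    contrast: tuple[float, float] = (0.9, 1.1)
    gamma: tuple[float, float] = (0.8, 1.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("segmentation", "detection"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.task == "detection":
            # invariant: detection never rotates or flips
            object.__setattr__(self, "rotation_deg", 0.0)
            object.__setattr__(self, "flip_axes", ())

    @classmethod
    def segmentation(cls, seed: int = 0, **kw) -> "AugPolicy":
        return cls(task="segmentation", seed=seed, **kw)

    @classmethod
    def detection(cls, seed: int = 0, **kw) -> "AugPolicy":
        return cls(task="detection", seed=seed, **kw)


@dataclass(frozen=True)
class TrainConfig:
    """Sliding-patch training knobs (desk-scale defaults)."""

    iterations: int = 200
    patch_size: int = 32
    batch_size: int = 1
    lr: float = 3e-3
    lr_final_fraction: float = 0.1  # linear decay target as a fraction of lr
    foreground_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 0 or self.patch_size <= 0 or self.batch_size <= 0:
            raise ValueError("iterations, patch_size and batch_size must be positive")


@dataclass
class CandidateNodule:
    """A detector box enriched with lobe assignment and, later, a contour."""

    box: Box3D
    score: float
    lobe: str | None = None
    lobe_overlap: float = 0.0
    contour: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lobe_overlap <= 1.0:
            raise ValueError("lobe_overlap must lie in [0, 1]")
        if (self.lobe is None) != (self.lobe_overlap == 0.0):
            raise ValueError("lobe is None exactly when lobe_overlap is 0")


@dataclass
class GuidanceOutcome:
    """Result of applying the EHR guidance signal to a candidate list."""

    retained: list[CandidateNodule]
    removed: list[CandidateNodule]
    masked_volume: Volume | None = None
    potential_false_negative: bool = False


# ---------------------------------------------------------------------------
# augmentation


def draw_aug_params(policy: AugPolicy, rng: np.random.Generator) -> dict:
    """Draw one set of augmentation parameters from the policy ranges."""
    r = policy.rotation_deg
    return {
        "angles_deg": tuple(float(a) for a in rng.uniform(-r, r, size=3)) if r > 0 else (0.0, 0.0, 0.0),
        "scale": float(rng.uniform(*policy.scale_range)),
        "flips": tuple(int(ax) for ax in policy.flip_axes if rng.random() < 0.5),
        "noise_sd": float(rng.uniform(0.0, policy.noise_sd_max)),
        "blur_sigma": float(rng.uniform(0.0, policy.blur_sigma_max)),
        "brightness": float(rng.uniform(*policy.brightness)),
        "contrast": float(rng.uniform(*policy.contrast)),
        "gamma": float(rng.uniform(*policy.gamma)),
    }


def _rotation_matrix(angles_deg: Sequence[float]) -> np.ndarray:
    az, ay, ax = [np.deg2rad(a) for a in angles_deg]
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    rz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])  # rotation about axis 0
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    return rz @ ry @ rx


def augment_sample(
    image: np.ndarray,
    target: np.ndarray | list[Box3D],
    policy: AugPolicy,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray | list[Box3D]]:
    """Apply one random augmentation draw identically to image and target.

    ``image`` is a window-normalised (D, H, W) array; ``target`` is either
    an integer label grid (segmentation) or a list of boxes (detection).
    Boxes are transformed as corner points and re-tightened to integer
    bounds; boxes pushed outside the grid are dropped.  With ``rng`` unset
    the policy seed is used, so the call is deterministic.
    """
    rng = rng if rng is not None else np.random.default_rng(policy.seed)
    params = draw_aug_params(policy, rng)
    shape = np.asarray(image.shape, dtype=float)
    center = (shape - 1.0) / 2.0

    rot = _rotation_matrix(params["angles_deg"])
    s = params["scale"]
    fwd = rot * s  # input -> output mapping about the center
    inv = np.linalg.inv(fwd)
    identity_spatial = np.allclose(fwd, np.eye(3))

    img = image.astype(np.float32)
    is_boxes = isinstance(target, list)
    if not identity_spatial:
        offset = center - inv @ center
        img = ndimage.affine_transform(img, inv, offset=offset, order=1, mode="constant", cval=0.0)
        if is_boxes:
            new_boxes = []
            for b in target:
                corners = np.array([[z, y, x] for z in (b.lo[0], b.hi[0]) for y in (b.lo[1], b.hi[1]) for x in (b.lo[2], b.hi[2])], dtype=float)
                moved = (fwd @ (corners - center).T).T + center
                lo = np.floor(moved.min(axis=0)).astype(int)
                hi = np.ceil(moved.max(axis=0)).astype(int)
                lo = np.clip(lo, 0, np.asarray(image.shape))
                hi = np.clip(hi, 0, np.asarray(image.shape))
                if np.all(hi > lo):
                    new_boxes.append(replace(b, lo=tuple(lo), hi=tuple(hi)))
            target = new_boxes
        else:
            target = ndimage.affine_transform(target, inv, offset=offset, order=0, mode="constant", cval=0)

    for ax in params["flips"]:
        img = np.flip(img, axis=ax)
        if is_boxes:
            n = image.shape[ax]
            target = [
                replace(
                    b,
                    lo=tuple(n - b.hi[i] if i == ax else b.lo[i] for i in range(3)),
                    hi=tuple(n - b.lo[i] if i == ax else b.hi[i] for i in range(3)),
                )
                for b in target
            ]
        else:
            target = np.flip(target, axis=ax)

    # intensity chain (image only)
    if params["blur_sigma"] > 0.05:
        img = ndimage.gaussian_filter(img, params["blur_sigma"])
    if params["noise_sd"] > 0:
        img = img + rng.normal(0.0, params["noise_sd"], size=img.shape).astype(np.float32)
    mean = float(img.mean())
    img = mean + params["contrast"] * (img - mean) + params["brightness"]
    img = np.clip(img, 0.0, 1.0) ** params["gamma"]
    if not is_boxes:
        target = np.ascontiguousarray(target)
    return img.astype(np.float32), target


# ---------------------------------------------------------------------------
# sliding-patch training


def _crop_padded(arr: np.ndarray, lo: Sequence[int], size: int, fill: float = 0.0) -> np.ndarray:
    """Crop a cube of side ``size`` at ``lo``, zero-padding outside the grid."""
    out = np.full((size, size, size), fill, dtype=arr.dtype)
    src = [slice(max(0, l), min(s, l + size)) for l, s in zip(lo, arr.shape)]
    dst = [slice(sl.start - l, sl.stop - l) for sl, l in zip(src, lo)]
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _sample_patch_origin(
    case: PhantomCase, patch: int, rng: np.random.Generator, foreground_fraction: float
) -> np.ndarray:
    shape = np.asarray(case.volume.shape)
    fg = np.argwhere(case.nodule_mask.labels > 0)
    if len(fg) and rng.random() < foreground_fraction:
        center = fg[rng.integers(len(fg))]
        lo = center - patch // 2 + rng.integers(-patch // 4, patch // 4 + 1, size=3)
    else:
        lo = rng.integers(-patch // 4, np.maximum(1, shape - 3 * patch // 4), size=3)
    return lo


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((n_classes, *labels.shape), dtype=np.float32)
    for c in range(n_classes):
        out[c] = labels == c
    return out


def train_model(
    model: SegmentationModel | DetectionModel,
    cases: Sequence[PhantomCase],
    cfg: TrainConfig,
    policy: AugPolicy,
    target: str = "auto",
) -> tuple[SegmentationModel | DetectionModel, list[float]]:
    """Train a model contract in place with sliding patches; returns loss trace.

    ``target`` selects the segmentation ground truth: ``"nodules"`` (binary
    foreground) or ``"lobes"`` (six classes); ``"auto"`` infers it from the
    model's class count.  Detection models train against the case's truth
    boxes.  A fixed ``cfg.seed`` reproduces the loss trace; a non-finite
    loss aborts with a diagnostic.
    """
    if not cases:
        raise ValueError("training requires at least one case")
    is_seg = isinstance(model, SegmentationModel)
    if target == "auto":
        target = "lobes" if (is_seg and model.cfg.n_classes > 2) else "nodules"
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(lr=cfg.lr)
    losses: list[float] = []
    patch = cfg.patch_size
    for it in range(cfg.iterations):
        opt.lr = cfg.lr * (1.0 - (1.0 - cfg.lr_final_fraction) * it / max(1, cfg.iterations - 1))
        loss_acc = 0.0
        for _ in range(cfg.batch_size):
            case = cases[int(rng.integers(len(cases)))]
            img_full = normalize_hu(case.volume.values)
            lo = _sample_patch_origin(case, patch, rng, cfg.foreground_fraction)
            img = _crop_padded(img_full, lo, patch)
            if is_seg:
                grid = case.nodule_mask.labels if target == "nodules" else case.lobes.labels
                lab = _crop_padded(grid, lo, patch).astype(np.int32)
                if target == "nodules":
                    lab = (lab > 0).astype(np.int32)
                img, lab = augment_sample(img, lab, policy, rng=np.random.default_rng(policy.seed + it))
                y = _one_hot(lab, model.cfg.n_classes)
                loss = model.train_step(img[None], y, opt)
            else:
                boxes = []
                for b in case.truth_boxes:
                    blo = np.asarray(b.lo) - lo
                    bhi = np.asarray(b.hi) - lo
                    clo = np.clip(blo, 0, patch)
                    chi = np.clip(bhi, 0, patch)
                    if np.all(chi > clo) and np.prod(chi - clo) >= 0.5 * b.volume:
                        boxes.append(replace(b, lo=tuple(int(v) for v in clo), hi=tuple(int(v) for v in chi)))
                img, boxes = augment_sample(img, boxes, policy, rng=np.random.default_rng(policy.seed + it))
                loss = model.train_step(img[None], boxes, opt)
            loss_acc += loss
        loss_acc /= cfg.batch_size
        if not np.isfinite(loss_acc):
            raise RuntimeError(f"training diverged at iteration {it}: loss={loss_acc}")
        losses.append(float(loss_acc))
    return model, losses


# ---------------------------------------------------------------------------
# inference


def _window_starts(extent: int, patch: int, step: int) -> list[int]:
    if extent <= patch:
        return [0]
    starts = list(range(0, extent - patch, step))
    starts.append(extent - patch)
    return sorted(set(starts))


def sliding_window_predict(
    model: SegmentationModel | DetectionModel,
    v: Volume,
    patch_size: int | None = None,
    overlap_fraction: float = 0.5,
    score_threshold: float = 0.5,
    nms_iou: float = 0.1,
):
    """Whole-volume inference by tiling fixed-size patches.

    Segmentation models return a (n_classes, D, H, W) probability map with
    overlapping patch predictions uniformly averaged; detection models
    return a globally suppressed candidate box list in volume coordinates.
    Volumes smaller than one patch are zero-padded and un-padded on output.
    """
    patch = patch_size or model.cfg.patch_size
    div = 2 ** (model.cfg.depth - 1)
    if patch % div:
        raise ValueError(f"patch size {patch} must be divisible by {div}")
    img = normalize_hu(v.values)
    shape = img.shape
    pad = [max(0, patch - s) for s in shape]
    if any(pad):
        img = np.pad(img, [(0, p) for p in pad])
    step = max(1, int(round(patch * (1.0 - overlap_fraction))))
    starts = [_window_starts(s, patch, step) for s in img.shape]

    if hasattr(model, "predict_proba"):  # segmentation contract
        acc = np.zeros((model.cfg.n_classes, *img.shape), dtype=np.float32)
        cnt = np.zeros(img.shape, dtype=np.float32)
        for z in starts[0]:
            for y in starts[1]:
                for x in starts[2]:
                    sl = (slice(z, z + patch), slice(y, y + patch), slice(x, x + patch))
                    acc[(slice(None), *sl)] += model.predict_proba(img[sl][None])
                    cnt[sl] += 1.0
        probs = acc / cnt
        return probs[:, : shape[0], : shape[1], : shape[2]]

    boxes: list[Box3D] = []
    for z in starts[0]:
        for y in starts[1]:
            for x in starts[2]:
                sl = (slice(z, z + patch), slice(y, y + patch), slice(x, x + patch))
                out = model.predict(img[sl][None])
                for b in decode_detections(out, score_threshold, nms_iou):
                    lo = (b.lo[0] + z, b.lo[1] + y, b.lo[2] + x)
                    hi = (b.hi[0] + z, b.hi[1] + y, b.hi[2] + x)
                    clo = tuple(min(l, s - 1) for l, s in zip(lo, shape))
                    chi = tuple(min(h, s) for h, s in zip(hi, shape))
                    if all(h > l for l, h in zip(clo, chi)):
                        boxes.append(replace(b, lo=clo, hi=chi))
    return nms(boxes, nms_iou)


def assign_lobe(box: Box3D, lobes: LabelMap) -> CandidateNodule:
    """Attach the argmax-overlap lobe to a candidate box.

    The lobe is the label with the largest voxel overlap inside the box
    (ties broken toward the lowest label index); ``lobe_overlap`` is that
    overlap divided by the box volume.  A box with no lung overlap gets
    ``lobe=None``.
    """
    clipped = box.clipped(lobes.shape)
    crop = lobes.labels[clipped.slices()]
    counts = np.bincount(crop.ravel(), minlength=6)
    counts = counts[1:6]  # labels 1..5
    if counts.sum() == 0:
        return CandidateNodule(box=box, score=box.score or 0.0, lobe=None, lobe_overlap=0.0)
    label = int(np.argmax(counts)) + 1  # argmax returns the first (lowest) max
    return CandidateNodule(
        box=box,
        score=box.score or 0.0,
        lobe=LABEL_TO_CODE[label],
        lobe_overlap=float(counts[label - 1] / clipped.volume),
    )


def lobe_contact_filter(cands: Sequence[CandidateNodule], min_overlap: float = 0.0) -> list[CandidateNodule]:
    """Keep candidates in contact with a lobe, preserving order.

    Contact means any nonzero overlap by default; ``min_overlap`` imposes a
    stricter fractional requirement.
    """
    return [c for c in cands if c.lobe is not None and c.lobe_overlap > min_overlap]


def ehr_guided_filter(
    cands: Sequence[CandidateNodule],
    confirmed: ExtractionResult,
    mode: str = "filter",
    volume: Volume | None = None,
    lobes: LabelMap | None = None,
) -> GuidanceOutcome:
    """Apply the EHR guidance signal to the candidate list.

    ``filter`` mode splits candidates into those inside a confirmed lobe
    (retained) and the rest (removed); counts are conserved and the
    operation is idempotent.  ``mask`` mode instead returns the volume with
    everything outside the confirmed lobes set to air, for re-detection
    restricted to the confirmed lobes.
    """
    if not confirmed.lobes:
        raise ValueError("guidance requires at least one confirmed lobe")
    bad = confirmed.lobes - set(LOBE_CODES)
    if bad:
        raise ValueError(f"invalid confirmed lobe codes: {sorted(bad)}")
    if mode == "filter":
        retained = [c for c in cands if c.lobe in confirmed.lobes]
        removed = [c for c in cands if c.lobe not in confirmed.lobes]
        return GuidanceOutcome(
            retained=retained, removed=removed, potential_false_negative=not retained
        )
    if mode == "mask":
        if volume is None or lobes is None:
            raise ValueError("mask mode requires the volume and lobe label map")
        keep = np.isin(lobes.labels, [LOBE_LABELS[c] for c in confirmed.lobes])
        masked = np.where(keep, volume.values, HU_AIR).astype(np.float32)
        return GuidanceOutcome(
            retained=[], removed=[], masked_volume=replace(volume, values=masked)
        )
    raise ValueError(f"unknown guidance mode {mode!r}")


def segment_candidates(
    model: SegmentationModel,
    v: Volume,
    retained: Sequence[CandidateNodule],
    crop_size: int = 64,
) -> list[CandidateNodule]:
    """Second stage: crop around each candidate and delineate its contour.

    Each crop is ``crop_size``^3, centered on the candidate's box center and
    zero-padded at volume borders; the predicted foreground is placed back
    into the global frame, restricted to the crop.  Boxes larger than the
    crop are center-clipped with a warning.
    """
    div = 2 ** (model.cfg.depth - 1)
    if crop_size % div:
        raise ValueError(f"crop size {crop_size} must be divisible by {div}")
    img = normalize_hu(v.values)
    out: list[CandidateNodule] = []
    for cand in retained:
        extent = max(h - l for l, h in zip(cand.box.lo, cand.box.hi))
        if extent > crop_size:
            warnings.warn(
                f"candidate box extent {extent} exceeds crop size {crop_size}; contour will be clipped",
                stacklevel=2,
            )
        center = np.asarray(cand.box.center)
        lo = np.round(center - crop_size / 2.0).astype(int)
        crop = _crop_padded(img, lo, crop_size)
        probs = model.predict_proba(crop[None])
        fg = probs.argmax(axis=0) > 0
        contour = np.zeros(v.shape, dtype=bool)
        src = [slice(max(0, l), min(s, l + crop_size)) for l, s in zip(lo, v.shape)]
        sub = [slice(sl.start - l, sl.stop - l) for sl, l in zip(src, lo)]
        contour[tuple(src)] = fg[tuple(sub)]
        out.append(replace(cand, contour=contour))
    return out
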