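"""Training losses and evaluation metrics for segmentation and detection.

Segmentation uses a dual loss — voxelwise categorical cross-entropy plus a
soft Dice loss — whose two terms sit in the same order of magnitude and are
simply added.  Detection uses a smooth-L1 (Huber) penalty on the mean
absolute box-coordinate error for the regression heads and a focal loss for
the anchor classification heads.  Evaluation reports the Dice similarity
coefficient (DSC) for masks and, for boxes, a single-class precision
TP/(TP+FP) at a fixed IoU threshold alongside the conventional all-point
average precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .imgio import Box3D

__all__ = [
    "EPS",
    "FocalParams",
    "DetectionEval",
    "cross_entropy",
    "dice_loss",
    "dual_seg_loss",
    "smooth_l1",
    "focal_loss",
    "dsc",
    "iou3d",
    "average_precision",
]

#: Smoothing constant used in logs and Dice denominators.
EPS = 1e-7


@dataclass(frozen=True)
class FocalParams:
    """Focal-loss parameters; defaults are the canonical RetinaNet settings."""

    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.gamma < 0.0:
            raise ValueError("gamma must be non-negative")


@dataclass
class DetectionEval:
    """Matching outcome of scored predictions against ground-truth boxes."""

    iou_threshold: float
    tp: int
    fp: int
    fn: int
    matches: list[tuple[int, int]] = field(default_factory=list)  # (pred_idx, truth_idx)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0


# ---------------------------------------------------------------------------
# segmentation losses


def _check_pair(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    return p, y


def cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """Categorical cross-entropy -sum_i y_i log p_i, averaged over voxels.

    ``p`` and ``y`` share a leading class axis; ``y`` is one-hot.  The mean
    is over voxels (not voxels x classes) so the term stays comparable in
    magnitude with the Dice loss.
    """
    p, y = _check_pair(p, y)
    n_vox = p[0].size if p.ndim > 1 else p.size
    return float(-(y * np.log(np.clip(p, EPS, 1.0))).sum() / n_vox)


def dice_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Soft Dice loss 1 - 2 sum(y p) / (sum y^2 + sum p^2 + eps).

    Accepts either plain foreground maps (any shape) or class-axis-leading
    stacks; with a class axis the loss is averaged over foreground classes
    (class index >= 1), matching the binary definition when there are two
    classes.
    """
    p, y = _check_pair(p, y)

    def one(pc: np.ndarray, yc: np.ndarray) -> float:
        num = 2.0 * float((yc * pc).sum())
        den = float((yc**2).sum() + (pc**2).sum()) + EPS
        return 1.0 - num / den

    if p.ndim == 4 and p.shape[0] >= 2:
        return float(np.mean([one(p[c], y[c]) for c in range(1, p.shape[0])]))
    return one(p, y)


def dual_seg_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Cross-entropy plus Dice loss; non-negative, 0 at a perfect prediction."""
    return cross_entropy(p, y) + dice_loss(p, y)


# ---------------------------------------------------------------------------
# detection losses


def _boxes_to_coords(boxes: list[Box3D] | np.ndarray) -> np.ndarray:
    if isinstance(boxes, np.ndarray):
        return np.asarray(boxes, dtype=np.float64)
    return np.asarray([[*b.lo, *b.hi] for b in boxes], dtype=np.float64)


def smooth_l1(
    pred_boxes: list[Box3D] | np.ndarray,
    true_boxes: list[Box3D] | np.ndarray,
    delta: float = 1.0,
    as_printed: bool = False,
) -> float:
    """Huber penalty applied to the mean absolute box-coordinate error.

    With MAE = mean |x_i - y_i| over all paired coordinates the loss is
    0.5 MAE^2 / delta when MAE < delta and MAE - 0.5 delta otherwise
    (continuous at MAE = delta).  ``as_printed=True`` multiplies instead of
    dividing by delta in the quadratic branch; the two coincide at the
    default delta = 1.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    xp = _boxes_to_coords(pred_boxes)
    yt = _boxes_to_coords(true_boxes)
    if xp.shape != yt.shape or xp.size == 0:
        raise ValueError("smooth_l1 requires equal, non-empty box pairings")
    mae = float(np.abs(xp - yt).mean())
    if mae < delta:
        return 0.5 * mae * mae * (delta if as_printed else 1.0 / delta)
    return mae - 0.5 * delta


def focal_loss(
    p: np.ndarray | float,
    y: np.ndarray | float,
    fp: FocalParams = FocalParams(),
    reduction: str = "mean",
) -> float:
    """Focal loss for binary anchor classification.

    ``-alpha (1-p)^gamma log p`` for positives and
    ``-(1-alpha) p^gamma log(1-p)`` for negatives; probabilities are clamped
    to [eps, 1-eps].  At gamma = 0, alpha = 0.5 this is half the standard
    binary cross-entropy.
    """
    p = np.clip(np.asarray(p, dtype=np.float64), EPS, 1.0 - EPS)
    y = np.asarray(y, dtype=np.float64)
    pos = -fp.alpha * (1.0 - p) ** fp.gamma * np.log(p)
    neg = -(1.0 - fp.alpha) * p**fp.gamma * np.log(1.0 - p)
    per = np.where(y >= 0.5, pos, neg)
    if reduction == "sum":
        return float(per.sum())
    if reduction == "none":
        return per  # type: ignore[return-value]
    return float(per.mean())


# ---------------------------------------------------------------------------
# evaluation metrics


def dsc(x: np.ndarray, y: np.ndarray, printed_form: bool = False) -> float:
    """Dice similarity coefficient 2|x∩y| / (|x|+|y|) of two binary masks.

    Both masks empty is a perfect (vacuous) agreement, scored 1.0.
    ``printed_form=True`` drops the factor 2 (|x∩y|/(|x|+|y|)).
    """
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    denom = int(x.sum()) + int(y.sum())
    if denom == 0:
        return 1.0
    inter = int((x & y).sum())
    return (1.0 if printed_form else 2.0) * inter / denom


def iou3d(a: Box3D, b: Box3D) -> float:
    """Intersection-over-union of two half-open voxel boxes."""
    inter = 1.0
    for (al, ah), (bl, bh) in zip(zip(a.lo, a.hi), zip(b.lo, b.hi)):
        ov = min(ah, bh) - max(al, bl)
        if ov <= 0:
            return 0.0
        inter *= ov
    union = a.volume + b.volume - inter
    return float(inter / union)


def _match_boxes(preds: list[Box3D], truth: list[Box3D], iou_threshold: float) -> list[tuple[int, int]]:
    """Optimal one-to-one matching of predictions to truth at an IoU floor.

    Maximises the number of matched pairs (maximum bipartite matching via
    the assignment solver), breaking ties toward higher total IoU, so the
    TP count equals the best achievable assignment.
    """
    if not preds or not truth:
        return []
    iou = np.array([[iou3d(p, t) for t in truth] for p in preds])
    valid = iou >= iou_threshold
    if not valid.any():
        return []
    # large constant reward per valid pair dominates the IoU tie-break
    score = valid * (10.0 + iou)
    rows, cols = linear_sum_assignment(-score)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if valid[r, c]]


def average_precision(
    preds: list[Box3D],
    truth: list[Box3D],
    iou_threshold: float = 0.5,
) -> tuple[DetectionEval, float, float]:
    """Single-class detection evaluation at a fixed IoU threshold.

    Returns ``(eval, precision, ap)``: the matching bookkeeping, the
    per-class precision TP/(TP+FP) — the headline single-class metric — and
    the conventional ranked all-point average precision as a secondary
    value.  An empty prediction set scores 0 on both.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    order = np.argsort([-(b.score if b.score is not None else 1.0) for b in preds], kind="stable")
    ranked = [preds[i] for i in order]
    matches = _match_boxes(ranked, truth, iou_threshold)
    tp = len(matches)
    fp = len(preds) - tp
    fn = len(truth) - tp
    ev = DetectionEval(
        iou_threshold=iou_threshold,
        tp=tp,
        fp=fp,
        fn=fn,
        matches=[(int(order[r]), c) for r, c in matches],
    )
    precision = ev.precision

    # secondary: ranked all-point AP with greedy best-IoU matching
    ap = 0.0
    if truth and ranked:
        taken: set[int] = set()
        tps = np.zeros(len(ranked))
        for i, p in enumerate(ranked):
            best_j, best_iou = -1, iou_threshold
            for j, t in enumerate(truth):
                if j in taken:
                    continue
                v = iou3d(p, t)
                if v >= best_iou:
                    best_j, best_iou = j, v
            if best_j >= 0:
                taken.add(best_j)
                tps[i] = 1.0
        cum_tp = np.cumsum(tps)
        prec = cum_tp / (np.arange(len(ranked)) + 1)
        rec = cum_tp / len(truth)
        # all-point interpolation
        ap = 0.0
        prev_r = 0.0
        for r in np.unique(rec[tps > 0]):
            ap += (r - prev_r) * prec[rec >= r].max()
            prev_r = r
    return ev, precision, float(ap)
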