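"""Volume / label-map containers, NIfTI I/O, and CT preprocessing.

The in-memory data model is deliberately small: a :class:`Volume` is a 3D
scalar grid of Hounsfield units with physical voxel spacing, a
:class:`LabelMap` is an integer grid aligned to it, and a :class:`Box3D` is
an axis-aligned box in voxel coordinates.  All grids use axis order
``(z, y, x)`` with axial slices along ``z``, 0-based voxel indices and
half-open boxes ``[lo, hi)``.

Preprocessing follows standard CT practice for nodule work: resampling to
isotropic 1 mm voxels, clipping intensities to the [-1000, 600] HU window,
and converting segmentation contours into tight bounding boxes for detector
training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "LabelMap",
    "Box3D",
    "HU_WINDOW",
    "clip_hu",
    "normalize_hu",
    "resample_isotropic",
    "mask_to_boxes",
    "load_volume",
    "load_labelmap",
    "save_volume",
    "save_labelmap",
    "read_boxes_jsonl",
    "write_boxes_jsonl",
]

#: Default intensity window for lung CT, in Hounsfield units.
HU_WINDOW = (-1000.0, 600.0)


@dataclass
class Volume:
    """3D scalar grid (HU) with physical spacing and origin, axes (z, y, x)."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("Volume requires a non-empty 3D grid")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class LabelMap:
    """Non-negative integer grid aligned with a paired :class:`Volume`."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise ValueError("LabelMap requires a non-empty 3D grid")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class Box3D:
    """Axis-aligned 3D box: ``lo`` inclusive, ``hi`` exclusive voxel indices."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    score: float | None = None
    class_id: int = 1

    def __post_init__(self) -> None:
        if not all(h > l for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"degenerate box: lo={self.lo} hi={self.hi}")

    @property
    def volume(self) -> int:
        return int(np.prod([h - l for l, h in zip(self.lo, self.hi)]))

    @property
    def center(self) -> tuple[float, float, float]:
        return tuple((l + h) / 2.0 for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]

    def clipped(self, shape: Sequence[int]) -> "Box3D":
        lo = tuple(int(np.clip(l, 0, s)) for l, s in zip(self.lo, shape))
        hi = tuple(int(np.clip(h, 0, s)) for h, s in zip(self.hi, shape))
        if not all(h > l for l, h in zip(lo, hi)):
            raise ValueError(f"box {self.lo}..{self.hi} lies outside grid {tuple(shape)}")
        return replace(self, lo=lo, hi=hi)

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# preprocessing


def clip_hu(v: Volume, lo: float = HU_WINDOW[0], hi: float = HU_WINDOW[1]) -> Volume:
    """Clip intensities to ``[lo, hi]`` HU (idempotent; interior unchanged)."""
    if lo >= hi:
        raise ValueError("lower clip bound must be below upper bound")
    return replace(v, values=np.clip(v.values, lo, hi))


def normalize_hu(values: np.ndarray, window: tuple[float, float] = HU_WINDOW) -> np.ndarray:
    """Map the HU window linearly onto [0, 1] for network input."""
    lo, hi = window
    return ((np.clip(values, lo, hi) - lo) / (hi - lo)).astype(np.float32)


def resample_isotropic(
    v: Volume | LabelMap,
    target_spacing_mm: float | Sequence[float] = 1.0,
) -> Volume | LabelMap:
    """Resample to the target voxel spacing, preserving physical extent.

    Volumes are interpolated trilinearly, label maps nearest-neighbour so no
    new labels are invented.  Inputs already at the target spacing are
    returned unchanged (bit-exact identity).
    """
    target = np.broadcast_to(np.asarray(target_spacing_mm, dtype=float), (3,)).copy()
    if np.any(target <= 0):
        raise ValueError("target spacing must be positive")
    spacing = np.asarray(v.spacing_mm, dtype=float)
    if np.allclose(spacing, target):
        return v
    grid = v.values if isinstance(v, Volume) else v.labels
    new_shape = np.maximum(1, np.round(np.asarray(grid.shape) * spacing / target)).astype(int)
    zoom = new_shape / np.asarray(grid.shape)
    order = 1 if isinstance(v, Volume) else 0
    out = ndimage.zoom(grid, zoom, order=order, mode="nearest", grid_mode=True)
    new_spacing = tuple(float(t) for t in target)
    if isinstance(v, Volume):
        return replace(v, values=out, spacing_mm=new_spacing)
    return replace(v, labels=out.astype(grid.dtype), spacing_mm=new_spacing)


def mask_to_boxes(m: LabelMap) -> list[Box3D]:
    """One tight bounding box per positive label, half-open convention."""
    boxes: list[Box3D] = []
    labels = m.labels
    if labels.max(initial=0) == 0:
        return boxes
    objects = ndimage.find_objects(labels)
    for idx, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        # find_objects bounds the label's full extent; tighten per label in
        # case another label's voxels stretched the slice
        sub = labels[slc] == idx
        if not sub.any():
            continue
        offs = [s.start for s in slc]
        nz = np.nonzero(sub)
        lo = tuple(int(o + a.min()) for o, a in zip(offs, nz))
        hi = tuple(int(o + a.max() + 1) for o, a in zip(offs, nz))
        boxes.append(Box3D(lo=lo, hi=hi, class_id=idx))
    return boxes


# ---------------------------------------------------------------------------
# NIfTI and JSON-lines I/O


def _from_nifti(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple, np.ndarray]:
    canonical = nib.as_closest_canonical(img)
    data = np.asanyarray(canonical.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI image, got shape {data.shape}")
    # canonical (x, y, z) -> internal (z, y, x)
    data = np.transpose(data, (2, 1, 0))
    zooms = canonical.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return data, spacing, np.asarray(img.affine)


def load_volume(path: str | Path) -> Volume:
    data, spacing, affine = _from_nifti(nib.load(str(path)))
    return Volume(values=data.astype(np.float32), spacing_mm=spacing, affine=affine)


def load_labelmap(path: str | Path) -> LabelMap:
    data, spacing, affine = _from_nifti(nib.load(str(path)))
    return LabelMap(labels=np.rint(data).astype(np.int32), spacing_mm=spacing, affine=affine)


def _to_nifti(grid: np.ndarray, spacing: Sequence[float]) -> nib.Nifti1Image:
    xyz = np.transpose(grid, (2, 1, 0))
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    return nib.Nifti1Image(xyz, affine)


def save_volume(v: Volume, path: str | Path) -> None:
    nib.save(_to_nifti(np.asarray(v.values, dtype=np.float32), v.spacing_mm), str(path))


def save_labelmap(m: LabelMap, path: str | Path) -> None:
    nib.save(_to_nifti(np.asarray(m.labels, dtype=np.int16), m.spacing_mm), str(path))


def write_boxes_jsonl(boxes: Iterable[Box3D], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for b in boxes:
            rec = {"lo": list(b.lo), "hi": list(b.hi), "score": b.score, "class": b.class_id}
            fh.write(json.dumps(rec) + "\n")


def read_boxes_jsonl(path: str | Path) -> list[Box3D]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            out.append(
                Box3D(
                    lo=tuple(int(x) for x in rec["lo"]),
                    hi=tuple(int(x) for x in rec["hi"]),
                    score=rec.get("score"),
                    class_id=int(rec.get("class", 1)),
                )
            )
    return out
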