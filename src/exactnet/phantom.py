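"""Synthetic thorax phantoms and paired synthetic clinical reports.

Every downstream stage — preprocessing, detection, lobe assignment,
EHR-guided filtering, candidate segmentation and the comparison experiment
— is exercised on data from this module, so nothing in the package needs a
download.  The phantom is deliberately simple anatomy: two ellipsoidal
lungs inside a soft-tissue body, each lung split by oblique planes into its
lobes (three right, two left), with spherical nodules seeded at declared
positions.  Hounsfield values sit inside the standard lung CT window so
intensity clipping is non-destructive for the targets: air -1000, soft
tissue ~40, parenchyma -850, solid nodules +20, ground-glass -600.

The report generator emulates the structure of free-text radiology and
pathology reports: exactly one determinate current-tumor sentence naming
the true lobe in full words, optional *indeterminate*-nodule distractors,
optional treatment-history distractors in past-tense phrasing, and a
pathology-style sentence listing malignant lymph stations.  Sentence order
and tumor/carcinoma/malignancy synonym choice are randomized per seed so a
rule extractor cannot latch onto one fixed phrase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imgio import Box3D, LabelMap, Volume, mask_to_boxes, save_labelmap, save_volume, write_boxes_jsonl
from .reports import LOBE_CODES, ExtractionResult, lobe_code_to_name

__all__ = [
    "LobeGeometry",
    "NoduleSpec",
    "PhantomSpec",
    "PhantomCase",
    "ReportSpec",
    "generate_phantom",
    "generate_report",
    "sample_center_in_lobe",
    "random_report_spec",
    "write_case",
]

#: lobe label values 1..5 in LOBE_CODES order
LOBE_LABELS = {code: i + 1 for i, code in enumerate(LOBE_CODES)}
LABEL_TO_CODE = {v: k for k, v in LOBE_LABELS.items()}

HU_AIR = -1000.0
HU_SOFT_TISSUE = 40.0
HU_PARENCHYMA = -850.0
HU_SOLID_NODULE = 20.0
HU_GROUND_GLASS = -600.0


@dataclass(frozen=True)
class LobeGeometry:
    """Two ellipsoidal lungs split by oblique planes into 3 right + 2 left lobes.

    All parameters are fractions of the grid extent; defaults give
    plausible lung proportions at any grid size.  Fissure fidelity is a
    non-goal — the construction only guarantees a correct lobe count and a
    clean partition.
    """

    body_semi: tuple[float, float, float] = (0.49, 0.44, 0.47)
    lung_semi: tuple[float, float, float] = (0.40, 0.30, 0.17)
    right_center_x: float = 0.30
    left_center_x: float = 0.70
    # fractional axial split points within each lung's extent
    right_splits: tuple[float, float] = (0.40, 0.62)
    left_split: float = 0.48
    fissure_slope: float = 0.18  # obliqueness of the fissure planes in y


@dataclass(frozen=True)
class NoduleSpec:
    """One seeded nodule: where it goes and how it renders."""

    lobe_code: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    mean_hu: float = HU_SOLID_NODULE
    texture: str = "solid"
    wall_adjacent: bool = False

    def __post_init__(self) -> None:
        if self.lobe_code not in LOBE_CODES:
            raise ValueError(f"unknown lobe code {self.lobe_code!r}")
        if self.radius_mm <= 0:
            raise ValueError("nodule radius must be positive")
        if self.texture not in ("solid", "ground_glass"):
            raise ValueError(f"unknown texture {self.texture!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic thorax; the seed determines everything."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lobe_geometry: LobeGeometry = field(default_factory=LobeGeometry)
    nodules: tuple[NoduleSpec, ...] = ()
    noise_sd_hu: float = 20.0
    seed: int = 0


@dataclass
class PhantomCase:
    """A generated phantom: volume + aligned lobe and nodule label maps."""

    volume: Volume
    lobes: LabelMap
    nodule_mask: LabelMap
    truth_boxes: list[Box3D]
    truth_lobes: list[str]
    spec: PhantomSpec


@dataclass(frozen=True)
class ReportSpec:
    """Description of one synthetic clinical report and its ground truth."""

    true_lobe: str
    tumor_size_mm: float = 14.0
    lymph_stations: tuple[str, ...] = ()
    indeterminate_lobes: tuple[str, ...] = ()
    history_lobes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for code in (self.true_lobe, *self.indeterminate_lobes, *self.history_lobes):
            if code not in LOBE_CODES:
                raise ValueError(f"unknown lobe code {code!r}")


# ---------------------------------------------------------------------------
# volume construction


def _ellipsoid(shape: Sequence[int], center: Sequence[float], semi: Sequence[float]) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    d = ((zz - center[0]) / semi[0]) ** 2 + ((yy - center[1]) / semi[1]) ** 2 + ((xx - center[2]) / semi[2]) ** 2
    return d <= 1.0


def _build_lobes(shape: Sequence[int], geom: LobeGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Return (lobe label grid, body mask)."""
    shape = tuple(int(s) for s in shape)
    center = [s / 2.0 for s in shape]
    body = _ellipsoid(shape, center, [f * s for f, s in zip(geom.body_semi, shape)])
    lung_semi = [f * s for f, s in zip(geom.lung_semi, shape)]
    labels = np.zeros(shape, dtype=np.int16)
    zz, yy, _ = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    for side, cx_frac in (("R", geom.right_center_x), ("L", geom.left_center_x)):
        c = [shape[0] / 2.0, shape[1] / 2.0, cx_frac * shape[2]]
        lung = _ellipsoid(shape, c, lung_semi) & body
        # axial position within the lung, tilted in y to mimic oblique fissures
        t = (zz - (c[0] - lung_semi[0])) / (2.0 * lung_semi[0])
        t = t + geom.fissure_slope * (yy - c[1]) / (2.0 * lung_semi[1])
        if side == "R":
            labels[lung & (t < geom.right_splits[0])] = LOBE_LABELS["RUL"]
            labels[lung & (t >= geom.right_splits[0]) & (t < geom.right_splits[1])] = LOBE_LABELS["RML"]
            labels[lung & (t >= geom.right_splits[1])] = LOBE_LABELS["RLL"]
        else:
            labels[lung & (t < geom.left_split)] = LOBE_LABELS["LUL"]
            labels[lung & (t >= geom.left_split)] = LOBE_LABELS["LLL"]
    return labels, body


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render a phantom thorax from its spec; bit-reproducible per seed.

    Raises ``ValueError`` naming the offending nodule if a nodule's center
    does not land inside its declared lobe.
    """
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    lobes, body = _build_lobes(shape, spec.lobe_geometry)
    lung = lobes > 0

    values = np.full(shape, HU_AIR, dtype=np.float32)
    values[body] = HU_SOFT_TISSUE
    values[lung] = HU_PARENCHYMA

    nodule_mask = np.zeros(shape, dtype=np.int16)
    coords = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    truth_lobes: list[str] = []
    for i, nod in enumerate(spec.nodules):
        center_vox = np.asarray(nod.center_mm) / spacing
        cidx = tuple(int(round(c)) for c in center_vox)
        if not all(0 <= c < s for c, s in zip(cidx, shape)):
            raise ValueError(f"nodule {i} ({nod.lobe_code}): center {nod.center_mm} mm outside grid")
        if lobes[cidx] != LOBE_LABELS[nod.lobe_code]:
            found = LABEL_TO_CODE.get(int(lobes[cidx]), "background")
            raise ValueError(
                f"nodule {i}: declared lobe {nod.lobe_code} but center {nod.center_mm} mm lies in {found}"
            )
        d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(coords, center_vox, spacing))
        sphere = d2 <= nod.radius_mm**2
        # nodules live in lung tissue; wall-adjacent ones may cross the pleura
        sphere &= body if nod.wall_adjacent else lung
        values[sphere] = nod.mean_hu
        nodule_mask[sphere] = i + 1
        truth_lobes.append(nod.lobe_code)
        if nod.wall_adjacent:
            # partial-volume blur at the pleural boundary
            lo = [max(0, int(c - nod.radius_mm / s - 3)) for c, s in zip(center_vox, spacing)]
            hi = [min(n, int(c + nod.radius_mm / s + 4)) for c, n, s in zip(center_vox, shape, spacing)]
            region = tuple(slice(l, h) for l, h in zip(lo, hi))
            values[region] = ndimage.gaussian_filter(values[region], sigma=1.0)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_hu > 0:
        values = values + rng.normal(0.0, spec.noise_sd_hu, size=shape).astype(np.float32)

    spacing_t = tuple(float(s) for s in spacing)
    case = PhantomCase(
        volume=Volume(values=values.astype(np.float32), spacing_mm=spacing_t),
        lobes=LabelMap(labels=lobes, spacing_mm=spacing_t),
        nodule_mask=LabelMap(labels=nodule_mask, spacing_mm=spacing_t),
        truth_boxes=[],
        truth_lobes=truth_lobes,
        spec=spec,
    )
    case.truth_boxes = mask_to_boxes(case.nodule_mask)
    if len(case.truth_boxes) != len(spec.nodules):
        raise ValueError("a seeded nodule rendered no voxels (radius below voxel size?)")
    return case


def sample_center_in_lobe(
    lobes: LabelMap,
    lobe_code: str,
    radius_mm: float,
    rng: np.random.Generator,
    avoid: Sequence[tuple[tuple[float, float, float], float]] = (),
    wall_adjacent: bool = False,
) -> tuple[float, float, float]:
    """Pick a nodule center (mm) inside a lobe with full-radius clearance.

    ``avoid`` lists (center_mm, radius_mm) of already placed nodules.  With
    ``wall_adjacent`` the center is instead placed so the sphere touches
    the lung boundary (clearance between 0.3 and 0.8 of the radius).
    """
    spacing = np.asarray(lobes.spacing_mm)
    inside = lobes.labels == LOBE_LABELS[lobe_code]
    if not inside.any():
        raise ValueError(f"lobe {lobe_code} is empty in this phantom")
    # distance (mm) to the nearest non-lung voxel, evaluated inside the lobe
    dist_lung = ndimage.distance_transform_edt(lobes.labels > 0, sampling=spacing)
    dist_lobe = ndimage.distance_transform_edt(inside, sampling=spacing)
    if wall_adjacent:
        ok = inside & (dist_lung > 0.3 * radius_mm) & (dist_lung < 0.8 * radius_mm) & (dist_lobe > 1.0)
    else:
        ok = inside & (dist_lobe > radius_mm)
    cand = np.argwhere(ok)
    if cand.size == 0:
        raise ValueError(f"no room for a {radius_mm} mm-radius nodule in lobe {lobe_code}")
    order = rng.permutation(len(cand))
    for idx in order:
        c_mm = tuple(float(v) for v in cand[idx] * spacing)
        if all(
            np.linalg.norm(np.subtract(c_mm, o_c)) > radius_mm + o_r + 1.0 for o_c, o_r in avoid
        ):
            return c_mm
    raise ValueError(f"could not place nodule in {lobe_code} without overlap")


# ---------------------------------------------------------------------------
# report construction

_TUMOR_SYNONYMS = ("tumor", "carcinoma", "malignancy")

_DETERMINATE_TEMPLATES = (
    "There is a determinate {size:.0f} mm {syn} involving the {name}",
    "The current determinate {syn} is located in the {name}, measuring {size:.0f} mm",
    "A {size:.0f} mm determinate {syn} is identified within the {name}",
)
_INDETERMINATE_TEMPLATES = (
    "An indeterminate nodule is noted in the {name}",
    "Indeterminate sub-centimeter nodule in the {name}; {syn} cannot be excluded, follow-up advised",
    "There is an indeterminate lesion in the {name}, too small to characterize",
)
_HISTORY_TEMPLATES = (
    "The patient previously underwent resection of a {syn} in the {name}",
    "Status post radiotherapy for a {syn} in the {name} in 2019",
    "History of treated {syn} in the {name}",
)


def generate_report(spec: ReportSpec) -> tuple[str, ExtractionResult]:
    """Render a synthetic report and its paired ground-truth extraction.

    The text always contains exactly one determinate current-tumor
    sentence naming the true lobe in full words; distractor and finding
    order, and synonym choice, are seed-randomized.
    """
    rng = np.random.default_rng(spec.seed)

    def pick(seq):
        return seq[int(rng.integers(len(seq)))]

    findings: list[str] = []
    findings.append(
        pick(_DETERMINATE_TEMPLATES).format(
            size=spec.tumor_size_mm, syn=pick(_TUMOR_SYNONYMS), name=lobe_code_to_name(spec.true_lobe)
        )
    )
    for code in spec.indeterminate_lobes:
        findings.append(
            pick(_INDETERMINATE_TEMPLATES).format(syn=pick(_TUMOR_SYNONYMS), name=lobe_code_to_name(code))
        )
    for code in spec.history_lobes:
        findings.append(
            pick(_HISTORY_TEMPLATES).format(syn=pick(_TUMOR_SYNONYMS), name=lobe_code_to_name(code))
        )
    rng.shuffle(findings)

    lines = ["CT chest with contrast. Findings:"]
    lines += [s + "." for s in findings]
    if spec.lymph_stations:
        stations = [f"station {s.upper()}" for s in spec.lymph_stations]
        verb = "is" if len(stations) == 1 else "are"
        lines.append(f"Pathology: {' and '.join(stations)} {verb} positive for malignancy.")
    lines.append("Impression: findings as above.")
    text = "\n".join(lines)

    truth = ExtractionResult(
        lobes={spec.true_lobe},
        lymph_stations=[f"station {s.upper()}" for s in spec.lymph_stations],
        provenance="truth",
        raw_response=text,
    )
    return text, truth


_STATION_POOL = ("2R", "4R", "4L", "7", "10R", "10L", "11R", "11L")


def random_report_spec(
    seed: int,
    n_indeterminate: int = 1,
    n_history: int = 1,
    n_stations: tuple[int, int] = (1, 2),
) -> ReportSpec:
    """Draw a seeded ReportSpec with distractors — corpus building block."""
    rng = np.random.default_rng(seed)
    true_lobe = LOBE_CODES[int(rng.integers(len(LOBE_CODES)))]
    n_st = int(rng.integers(n_stations[0], n_stations[1] + 1))
    stations = tuple(rng.choice(_STATION_POOL, size=n_st, replace=False).tolist())
    return ReportSpec(
        true_lobe=true_lobe,
        tumor_size_mm=float(rng.integers(8, 30)),
        lymph_stations=stations,
        indeterminate_lobes=tuple(rng.choice(LOBE_CODES, size=n_indeterminate).tolist()),
        history_lobes=tuple(rng.choice(LOBE_CODES, size=n_history).tolist()),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# on-disk layout


def write_case(case: PhantomCase, out_dir: str | Path, report: tuple[str, ExtractionResult] | None = None) -> None:
    """Write a phantom case (and optional report) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_volume(case.volume, out / "volume.nii.gz")
    save_labelmap(case.lobes, out / "lobes.nii.gz")
    save_labelmap(case.nodule_mask, out / "nodules.nii.gz")
    write_boxes_jsonl(case.truth_boxes, out / "truth_boxes.jsonl")
    (out / "truth_lobes.json").write_text(json.dumps(case.truth_lobes))
    if report is not None:
        text, truth = report
        (out / "report.txt").write_text(text, encoding="utf-8")
        (out / "report_truth.json").write_text(
            json.dumps({"lobes": sorted(truth.lobes), "lymph_stations": truth.lymph_stations})
        )
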