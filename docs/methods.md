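# Methods

## Problem and approach

Automatic lung-nodule detection on CT suffers from false positives:
vessels, pleural irregularities and scanner noise produce candidate
nodules that are not the tumor under treatment, and not every real nodule
is the malignancy a radiotherapy plan targets.  The package implements a
two-stage detection + segmentation pipeline in which the patient's own
clinical reports supply prior knowledge: the lobe of the confirmed tumor
and the malignant lymph stations are parsed from free text and used to
remove candidates outside the confirmed lobe before contours are drawn.

The pipeline is:

1. **Preprocess** — resample the CT to isotropic 1 mm voxels (trilinear for
   intensities, nearest-neighbour for label maps) and clip intensities to
   [-1000, 600] HU.
2. **Detect** — a Retina-UNet3D (UNet3D encoder + feature-pyramid decoder
   with shared box-classification and box-regression heads) run as a
   sliding window over the volume; per-patch candidates are shifted to
   global coordinates and non-maximum-suppressed.
3. **Lobe assignment and contact filter** — each candidate box gets the
   lobe label with the largest voxel overlap inside the box; candidates
   overlapping no lobe at all are discarded.
4. **EHR guidance** — the report parser returns the confirmed lobe set;
   in `filter` mode candidates outside confirmed lobes are removed (the
   default: the worked clinical example removes already-detected
   candidates), in `mask` mode the volume outside confirmed lobes is set
   to air and detection is re-run on the masked volume.  Both modes are
   provided because the clinical description is compatible with either.
5. **Segment** — a 64^3 crop (configurable) centered on each surviving
   candidate is passed to a UNet3D that delineates the nodule contour,
   placed back into the global frame.

## Losses and metrics

Segmentation trains on a **dual loss**: voxel-averaged categorical
cross-entropy `-mean_v sum_c y_c log p_c` plus a soft Dice loss
`1 - 2*sum(y p) / (sum y^2 + sum p^2 + eps)`.  The mean (rather than sum)
over voxels keeps the two terms in the same order of magnitude, which is
why they can simply be added.  With more than two classes the Dice term is
averaged over foreground classes.  `eps = 1e-7` guards empty masks.

Detection trains on a **focal loss** for anchor classification
(`-alpha (1-p)^gamma log p` for positives, mirrored for negatives;
defaults alpha 0.25, gamma 2 — the canonical settings of the focal-loss
paper) and a **smooth-L1 penalty applied to the MAE** of the box deltas:
with `MAE = mean |x_i - y_i|`, the loss is `0.5 MAE^2 / delta` below
`delta` and `MAE - 0.5 delta` above, continuous at the joint; `delta = 1`.
(A published variant multiplies rather than divides by `delta` in the
quadratic branch; the two coincide at `delta = 1`, and the divide form —
the one in the originating detection literature — is the default, the
other available via `as_printed=True`.)

Evaluation reports the **Dice similarity coefficient**
`2|x∩y|/(|x|+|y|)` (defined as 1 when both masks are empty; a printed
variant without the factor 2 is available behind `printed_form=True`) and,
for detection, the **single-class precision** `TP/(TP+FP)` at a fixed IoU
threshold.  Matching is solved as a maximum one-to-one assignment
(assignment solver over IoU-valid pairs), so the TP count equals the best
achievable matching — this is verified in the tests against exhaustive
enumeration on all instances with up to five boxes.  The conventional
ranked all-point AP is reported alongside as a secondary metric.

## Networks

No GPU framework is assumed: the networks are a compact numpy
implementation (im2col 3x3x3 convolutions, leaky-ReLU, 2x average pooling
down / nearest-neighbour up, Adam) with hand-derived backward passes that
are finite-difference-checked in the test suite.  Channel width doubles
per level (capped at 8x base).  The detector attaches one cubic anchor per
pyramid-level cell (levels at strides >= 4; anchor edges default 8/16/32 mm
for three levels), encodes boxes as center offsets and log extents
relative to the anchor edge, and initialises the objectness bias to -2 so
the focal loss is not swamped by easy negatives at the start.  Anchor
matching uses IoU >= 0.2 positive / < 0.1 negative with the in-between
band ignored, and the best anchor of each ground-truth box forced
positive.  Default decoding threshold is 0.5 and NMS IoU 0.1 — the
detector is deliberately restrictive about false positives, and the
threshold is a first-class config knob precisely because lowering it
trades missed nodules for extra candidates that the guidance filter can
then remove.

All models are fully convolutional: any input whose sides are divisible by
`2^(depth-1)` is accepted, including anisotropic shapes (the lobe variant
of the segmenter runs on axially coarser grids with six classes and no
code change).

## Synthetic phantoms and reports

The phantom generator is the package's study population.  It emulates the
data regime the pipeline targets — isotropic 1 mm CT with annotated
nodules >= 3 mm and a five-lobe label map — with deliberately simple
anatomy: two ellipsoidal lungs in a soft-tissue body, each split by
oblique planes into 3 right + 2 left lobes.  HU values are air -1000,
soft tissue +40, parenchyma -850, solid nodules +20, ground-glass -600
(all inside the clip window, so clipping never destroys a target), plus
additive Gaussian noise (default SD 20 HU).  Note the consequence for
learning: a solid nodule (+20) is nearly isointense with body soft tissue
(+40), so the networks must use lung context, not a global threshold —
the phantom is easy geometry but not a trivially separable intensity
task.  Wall-adjacent nodules are rendered touching the pleura with a
partial-volume Gaussian blur, reproducing the hardest reported failure
mode as a test fixture.

What the phantom does **not** model: airways, vessels, real fissure
geometry, respiratory/cardiac motion, scanner artefacts, and nodule
texture heterogeneity.  Passing tests on phantoms therefore demonstrates
the correctness and the logic of the workflow (detection, lobe
assignment, guidance filtering, accounting), not clinical-grade detection
performance.

The report generator produces English template sentences with randomized
ordering and synonym choice among tumor/carcinoma/malignancy, exactly one
determinate current-tumor sentence naming the true lobe in full words,
plus two distractor classes — *indeterminate* nodules and past-tense
treatment history — and a pathology-style sentence listing malignant
lymph stations.  The distractor classes mirror the three keywords the
zero-shot prompt relies on (current / determinate / the synonym list).
The rule-based extractor scans sentence-wise for lobe mentions
co-occurring with tumor words, excluding indeterminate-qualified and
history-context sentences (lexical cues: "previously", "status post",
"history of", dated phrases).  This lexical envelope is sufficient for
the synthetic corpus by construction; free-form real reports would need
the language-model backend, which is specified as an injected client
contract (temperature 0, the exact prompt strings in
`reports.build_prompts`) and never exercised against a live service in
tests.

## Experiment protocol and accounting

`experiment.run_experiment` executes the full workflow per case and scores
it twice.  **Unguided match**: the raw detection count equals the number
of true tumors with no extraneous detection.  **Guided match**: the
retained count equals the truth with no false negative.  A false-positive
flag on a detection count that equals the truth cannot be inferred from
counts alone; the count-based record constructor therefore accepts it as
an explicit annotation (this is exactly the situation of the reference
accounting's last case, where the single detection was spurious and the
guidance removed it, leaving a false negative).  An optional stricter mode
requires each counted detection to hit a distinct truth box at a given
IoU, usable on phantoms where localization is checkable.  The summary
reports both rates in percent and the relative boost
`100*(guided - unguided)/unguided`, undefined (not infinite) when the
unguided rate is zero.

## Desk-scale training settings

The reference training regime for this architecture is 500k iterations at
96^3 patches on a GPU; this package's defaults are chosen to train in
minutes on one CPU and are config knobs, not constants:

| knob | desk default | note |
|---|---|---|
| phantom grid | 64^3 at 1 mm | cohort of ~20 cases |
| patch size | 24^3 | divisible by 2^(depth-1) = 4 |
| base channels / depth | 4 / 3 | ~2.2e4 (seg) / ~5e4 (det) parameters |
| segmenter iterations | 800, Adam lr 3e-3 | linear decay to 0.1x |
| detector iterations | 600, Adam lr 2e-3 | |
| foreground-biased sampling | 0.8 | rest uniform |
| sliding-window overlap | 0.5 | uniform averaging |

Augmentation policies default to the full regime (rotations +/-30 deg per
axis, scaling 70-140%, flips, noise/blur/brightness/contrast/gamma for
segmentation; the same minus rotation and flips for detection).  At a few
hundred iterations the full spatial policy prevents the tiny networks
from converging — the nodule/soft-tissue isointensity makes the task
context-dependent, and context varies too fast under heavy rotation for
this parameter budget — so the desk-scale training runs in the tests and
examples use the intensity-only subset.  This is a budget choice of the
desk-scale configuration, not a change to the policy defaults.

With these settings the held-out phantom cohort gives nodule DSC well
above 0.9 and the detector recovers the seeded nodules at scores near 1;
the guided-vs-unguided comparison then reduces to the guarantee that the
filter never removes a candidate in a confirmed lobe, so the guided match
rate dominates the unguided one whenever the reports are correct.

## Numerical choices and edge cases

- Boxes are half-open `[lo, hi)` in 0-based (z, y, x) voxel indices
  everywhere; IoU and rasterization use the same convention.
- Label-map resampling is nearest-neighbour (interpolation would invent
  labels); the label set after resampling is a subset of the input's.
- Lobe assignment ties break toward the lowest label index; "contact"
  with a lobe is any nonzero overlap by default, with a stricter
  fractional threshold available.
- Candidates whose box exceeds the segmentation crop are center-clipped
  with a warning (gross, advanced disease is outside the design
  envelope).
- `AP` of an empty prediction set is 0, not undefined; `DSC` of two empty
  masks is 1.
- Probabilities are clamped to `[1e-7, 1 - 1e-7]` inside logs.
- Training aborts with a diagnostic on a non-finite loss; seeds determine
  phantom content, report text, patch sampling, augmentation draws and
  weight init, so traces reproduce bit-for-bit on a fixed platform.

## Known limitations

- The numpy networks are single-sample and CPU-bound; they are meant for
  correctness and desk-scale experiments, not throughput.
- The rule-based extractor is a lexical system: negation scope, unusual
  phrasing and non-English text are out of its envelope (the injected
  LLM client is the path for real reports).
- The phantom's lobe geometry is schematic; lobe-boundary effects (e.g.
  candidates straddling a fissure) are only coarsely represented.
- Multifocal disease is supported in the data model (confirmed-lobe sets,
  multiple tumors per case) but the bundled cohorts seed one tumor per
  case.
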