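# Methods

`cpemip` implements a fully automatic pipeline that recognises chronic
pulmonary embolism (CPE) from CT pulmonary angiography (CTPA): the lungs
are segmented and masked, each lung is rendered as a set of rotational 2D
maximum intensity projections (MIPs), a view-averaging neural classifier
scores each lung, the left and right scores are fused by their maximum,
several independently trained models are ensembled by softmax averaging,
and a sliding-patch occlusion probe maps the decision back into scanner
space.  A synthetic vascular phantom generator provides labeled cohorts so
the entire pipeline is exercisable and testable without any clinical data.

## Rationale and model

CPE is recognised radiologically not from a visible clot but from
vascular remodelling: calibre variation and abrupt narrowing of pulmonary
arteries, reduction of distal vessels, and proximal tortuosity.  MIP
images of a masked lung show the contrast-filled vascular tree at a
glance, so the overall morphology can be classified from a handful of 2D
projections instead of the much harder problem of 3D vessel segmentation.

The classifier follows a multi-view transfer-learning design.  Each of
the 11 projection images of one lung is mapped to a feature vector by a
convolutional backbone; the 11 vectors are averaged element-wise (which
makes the prediction invariant to view order) and classified by a
three-layer perceptron — linear → ReLU → alpha-dropout → batch-norm,
twice, then a linear layer with a two-class softmax.  Both lungs of a
study are scored independently with the study label; at test time the
patient-level score is LR_max = max(p_left, p_right), reflecting that the
disease may affect either or both lungs.  Five models trained with
different seeds are combined by averaging their softmax outputs per lung
before fusion.

Because no deep-learning runtime is a dependency of this package, the
layers (strided conv, dense, batch-norm, alpha-dropout, Adam) are
implemented directly on numpy in `cpemip.nn`; gradients are verified
against finite differences in the test suite.  The bundled backbone
(`tiny-cnn-test`, three strided 3×3 convolutions with global max pooling,
32 features) is small enough to train on a laptop CPU and trains
end-to-end by default.  Max pooling (rather than average pooling) is a
deliberate choice: each feature then encodes the strongest local vascular
pattern anywhere in the view instead of the total vessel mass, so the
classifier cannot collapse onto a "fewer bright pixels = diseased"
shortcut.  That matters for calibre/tortuosity sensitivity and above all
for occlusion attribution, where most of the lung is blanked out and a
mass-coupled feature would read every patch as extreme distal pruning.  An ImageNet-pretrained backbone such as
DenseNet-121 can be plugged in as a frozen custom callable
(`create_feature_extractor(callable)`); in that configuration only the
head trains and per-view features are cached, exactly as in the
frozen-backbone transfer-learning setting the architecture was designed
for.

## Coordinate conventions and rendering

* Volumes are reoriented to RAS+ on ingest; voxel values are Hounsfield
  units clipped to [−1024, 3071].  Axis 0 is left→right, axis 1
  posterior→anterior, axis 2 inferior→superior.
* The view scheme is two fans sharing the anteroposterior start view:
  rotations of 0–150° in 30° steps about the vertical axis and about the
  left-right horizontal axis, 6 + 6 − 1 = 11 directions.  Sweep, step and
  the (one-sided) start are configurable; the one-sided reading is the
  only one consistent with an 11-view count.
* The transfer function is a monotone piecewise-linear ramp from HU to
  [0, 1]; the default window [−100, 500] HU zeroes parenchyma
  (≈ −850 HU) and saturates contrast-enhanced vessels (≳ +300 HU).  The
  original colour/opacity transfer was tuned visually and is not
  published; this scalar window is the package's own stand-in and is
  config-exposed.
* Projection is orthographic: the masked, transferred volume is cropped
  to the lung bounding box, resampled to isotropic spacing (`iso_mm`,
  default 1 mm), zero-padded to a rotation-safe cube, rotated by the view
  angle (trilinear interpolation), and reduced by the per-ray maximum
  along the antero-posterior axis.  Images are letterboxed to a square
  (`out_px`, default 224 px) and lie in [0, 1] by construction of the
  transfer ceiling; no per-image histogram stretching is applied, so
  intensities stay comparable across views and studies.
* Augmentation jitters each view by uniform ±3° in-plane (2D) and
  uniform ±10° about both volume rotation axes (3D), drawn from a seeded
  generator.  The distribution is uniform; only the magnitudes are
  prescribed.

## Lung masking

`method="external_file"` consumes any left/right lung mask NIfTI (e.g.
from a dedicated segmentation network), keeping that tool external.  The
built-in `threshold` fallback — adequate for phantoms and well-aerated
chests — thresholds at −400 HU, discards components touching the volume
border (outside air), keeps the two largest interior components, seals
the hilar opening with a ~12 mm morphological closing, fills internal
holes so intrapulmonary vessels and bronchi are retained, and assigns
left/right from the world-x centroid.  Masking sets everything outside
the selected lung to −1024 HU; it is idempotent, and the left/right
supports are disjoint by construction.

## Synthetic phantoms

Each phantom is a water-density body (+40 HU) containing two ellipsoidal
lungs at parenchymal density (−850 HU) with Gaussian noise (sd 20 HU),
each perfused by a recursive bifurcating vessel tree at +300 HU whose
radii taper by Murray's law (child = parent·2^(−1/3)).  Geometry scales
with the field of view; the default study grid is 64³ voxels at 4 mm
spacing (256 mm FOV).  The label controls morphology only:

* **NEG** — smooth, fully developed tree (2^depth terminal tips,
  depth 6 by default);
* **CPE** — sinusoidal centerline tortuosity (amplitude 6 mm), abrupt
  calibre steps (probability 0.3 per branch, factor 0.55), and removal of
  branches beyond half the tree depth with probability 0.5 — the
  pruning/narrowing/tortuosity triad a reader uses;
* **APE** — NEG morphology plus short soft-tissue-density filling
  defects (≈ +55 HU) in proximal branches: fresh clot without
  remodelling, so the CPE-vs-rest decision must rest on morphology, not
  on detecting emboli.

The generator emulates the geometry and HU contrast that masking,
windowing and projection must handle, and a class-conditional morphology
signal strong enough to be learnable from ~100 studies.  It does **not**
emulate airways, fissures, cardiac chambers, mosaic perfusion texture,
respiratory/streak artefacts, scanner spectra or realistic anatomical
variability — so green end-to-end tests demonstrate that the pipeline's
machinery recovers a known generative signal at desk scale, not that the
classifier would reach any particular accuracy on clinical CTPA.

## Training and evaluation

Splits are stratified by label and made at study level, so the two lungs
of a patient always share a subset; a leakage audit runs on every plan.
Five-fold cross-validation with a separate early-stopping set is
available for model selection.  Training treats each lung as an
independent example with the study label, reshuffles example order every
epoch from the seeded generator, uses two-class cross-entropy with Adam
(default learning rate 1e-4, batch 8 — the original optimiser settings
are unpublished), and writes a checkpoint plus the early-stopping-set
LR_max AUC after every epoch.  Checkpoint selection maximises
selection-set AUC with ties broken toward the earliest epoch; passing a
different selection set re-scores all checkpoints ("local early
stopping").

Evaluation computes the empirical ROC (trapezoidal AUC, equal to the
tie-corrected rank statistic), selects the operating point nearest the
top-left corner (ties toward higher specificity — the tie rule is this
package's choice), and reports balanced accuracy BAcc =
(sensitivity + specificity)/2 in two modes (each lung as a case, or one
LR_max case per study) under two threshold policies: *ad hoc*
(threshold from a held-out reference set) and *post hoc* (threshold from
the evaluated set itself, an in-set optimum that upper-bounds the ad hoc
value).  Reported scores are rounded to two decimals.

## Occlusion localization

An 80×80×80 mm cube slides through the volume (default stride 40 mm,
i.e. half-overlap for smoother maps; the stride is configurable and the
coverage requirement is only that the lattice covers the volume);
everything outside the patch is set to −1024 HU, the occluded volume goes
through the ordinary mask/render/predict path, and each voxel of the
output map keeps the maximum probability over the patches containing it.
Boxes are clipped at the volume boundary so the map shares the source
grid and affine and overlays the CTPA in any viewer; 0.80 is the default
display threshold for binarized maps.  Patches that do not intersect the
selected lung would render a blank view set whose prediction carries no
information about those voxels, so they are skipped and left at 0.  The
parenchyma-removal probe (`threshold_parenchyma`) sets voxels below
−500 HU to air; with the default vessel window (which already zeroes
everything below −100 HU) the rendered views are bit-identical, which the
tests assert exactly.

## Desk-scale experiment sizes and numerical choices

The bundled end-to-end experiment (`experiments.run_synthetic_experiment`)
uses 60 train / 15 early-stop / 30 test phantom studies at 64³ voxels and
4 mm spacing, rendered at `iso_mm=4`, `out_px=64`, five runs of up to 10
epochs with the tiny backbone at learning rate 1e-3 (a shorter, slightly
hotter schedule than the 30-epoch default, chosen once for the small
cohort), plus a study-level label-shuffled control trained identically.
The localization probe uses ten unilateral-CPE phantoms and scores a hit
when the highest-probability lung voxel of the combined left+right map
lies in the diseased lung.  All randomness (phantom seeds, weight
initialisation, shuffling, dropout, augmentation) flows through numpy
Generators derived from a single master seed; identical seeds reproduce
volumes, loss curves and predictions bit-for-bit.

Degenerate inputs are rejected rather than guessed at: single-class label
sets (AUC undefined), empty lungs, non-invertible affines, sweeps not
divisible by the step, strides exceeding the patch edge, and grids too
small to contain lungs all raise typed errors.

## Known limitations

* The phantom's realism gap (above) means desk-scale AUCs say nothing
  about clinical performance.
* The transfer function is a scalar window, not the original
  colour/opacity transfer; rendered appearance differs from the
  visually tuned original.
* The tiny backbone has 32 features; with a frozen pretrained backbone
  the head input would be ~1024-dimensional and the default head widths
  (256, 64) were chosen with that in mind.
* The threshold lung masker assumes air-filled lungs separated from
  outside air; severe consolidation or pleural contact with the body
  surface defeats it — supply an external mask in that case.
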