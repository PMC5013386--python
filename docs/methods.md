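# Methods

`biofilmquant` quantifies biofilm area and biofilm-removal efficiency from
paired before/after scanning electron micrographs of biomaterial surfaces.
This note describes the model behind each stage, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the design
choices made where the protocol left the design open.

## The measurement model

A field of view is imaged at an effective pixel size of 250 nm before and
after a biofilm-removal treatment. The analysis estimates, for each pair,

    percent remaining = 100 * A_after / A_before

where `A` is the biofilm pixel area of the binary segmentation of each
frame (`percent removed = 100 − percent remaining`). Everything else in the
package exists to make those two areas comparable and trustworthy:
registration puts both frames on the same pixel grid, preprocessing
normalizes each surface class's appearance, trainable pixel classification
produces the masks, post-filtering removes speckle noise, and the
validation harness measures how good the masks are.

The positive class is always biofilm (mask value 1, rendered white); the
negative class is the bare surface.

## Rigid registration

Stage relocation between SEM sessions leaves a small rigid offset between
frames. Scale-space keypoints (SIFT) are detected in both frames, matched
by nearest descriptor with a ratio test and cross-check, and a
rotation-plus-translation model is fitted by random-sample consensus over
minimal two-match samples (1000 trials, seeded), keeping matches whose
residual is at most `max_alignment_error` — 8 px by default, the geometric
consensus bound of the protocol — followed by a least-squares refit on the
inlier set. The after frame is resampled into the before frame (bilinear
for images; nearest-neighbour transport is used wherever masks are moved)
and both frames are cropped to the maximal axis-aligned rectangle free of
out-of-frame pixels, so downstream pixel-wise comparison never sees blank
corners. Transforms are parameterized as a rotation about the image center
plus a translation, which keeps rotation and translation errors
interpretable independently.

Recovery accuracy on synthetic pairs (translations up to 20 px, rotations
up to 5 degrees) is well under 1 px and 0.01 rad; registering an
already-registered pair returns the identity within tolerance.

## Surface-specific preprocessing

Two fixed filter chains, in their stated order:

* **SLA** (sandblasted/acid-etched, rough): sliding-paraboloid background
  subtraction with radius 1000 px, 1% saturated contrast stretch,
  bright-outlier removal (threshold 50, radius 2), gamma 0.6, 3×3 sharpen.
* **Polished**: 0.4% saturated contrast stretch, then outlier removal with
  threshold 0 and radius 2, which replaces every pixel brighter than its
  local median and so flattens thin bright scratches that would otherwise
  be read as bacteria.

Numerical conventions: all filters act in the 8-bit domain with reflected
borders; the outlier rule is strict (`pixel − median > threshold`), and its
polarity is bright-only; gamma acts on [0,1]-normalized intensities (for an
endpoint-preserving power law the normalized and raw forms coincide after
rescaling, so this choice is cosmetic); the sharpen kernel is −1 everywhere
with +12 at the center, divided by 4.

**Background subtraction.** The background is the lower envelope traced by
sliding a paraboloid of curvature `1/(2·radius)` (intensity levels per
px²) under the image surface. Because a rotationally symmetric paraboloid
is the separable choice of structuring function, the exact 2-D envelope
factorizes into 1-D parabolic erosions and dilations along rows and
columns; each 1-D pass is the linear-time lower-envelope transform
(numba-compiled). This replaces the directional-approximation scheme used
by interactive tools with the exact morphology the approximation targets.
A flat-ball variant (grayscale opening with a flat disc) is available by
flag. Consequences worth knowing: a radius-`R` paraboloid can only track
background whose concavity is gentler than `1/(2R)` levels/px², so
radius 1000 removes near-planar illumination gradients but deliberately
passes texture at the scale of the etched grain.

**Pairwise contrast consistency.** The saturated stretch is defined
per-image, but a classifier trained on the before frame is applied to the
after frame. If each frame stretched its own histogram, a biofilm-poor
after frame would expand its narrow surface histogram across the full
range and present the classifier with an alien intensity distribution —
in testing this inflated a fully-cleaned pair from the true 0% remaining
to ~150%. The pipeline therefore computes the stretch cutoffs once on the
before frame (after its background subtraction, for SLA) and replays the
same linear mapping on the after frame. Single-image use of
`enhance_contrast`/`apply_preset` retains the ordinary per-image rule.

## Feature stack and pixel classification

Each pixel is described by a bank of filter responses at the scale ladder
σ ∈ {1, 2, 4, 8, 16} (powers of two between the minimum sigma 1.0 and the
maximum 16.0). The default member set — Gaussian blur, Sobel gradient
magnitude of each blurred plane, Hessian (two eigenvalues and the
Frobenius module per scale), differences of Gaussians for every scale
pair, membrane projections (19×19 line kernels of thickness 1 at 30
orientations, with sum/mean/std/median/max/min projections across
orientations), and disc-neighborhood variance, mean, minimum, maximum and
median at radius σ, plus a bilateral smoother on a (spatial 5, 10) ×
(range 50, 100) grid — yields 71 planes including the original image. An
extended set for hard images adds Laplacian, first-order derivatives,
structure-tensor eigenvalues, local entropy and 8-directional
shifted-neighbour planes (141 planes). Anisotropic diffusion, Lipschitz,
Kuwahara and Gabor members are not implemented. Plane order is a pure
function of the configuration; a short fingerprint of the configuration is
stored with every trained classifier and checked at prediction time.

The classifier is a random forest: 200 trees, bootstrap per tree, random
feature subset of size `floor(log2(n_features)) + 1` per split, fixed
seed; training samples are the per-pixel feature vectors of 12×12-px ROI
squares labelled biofilm or surface (144 rows per ROI, 10–20 ROIs
typical). The per-pixel biofilm probability is the ensemble vote fraction
and the mask is `probability > 0.5`. Tree count and per-split width follow
the common defaults of randomized-forest segmentation tools; both are
recorded in the classifier container.

Two training-label modes exist. In ROI-label mode every pixel in an ROI
inherits the ROI's label — the operator workflow. In harness mode, used by
the synthetic experiments, each ROI pixel takes its label from the
ground-truth mask, so ROIs may legitimately straddle boundaries; this
matters because class-pure ROIs can only be placed in blob interiors,
whose large-scale neighborhood features differ from those of peripheral
pixels.

Post-processing removes connected components with strictly fewer than 20
pixels (8-connectivity). Mask polarity is fixed at training time
(1 = biofilm), so no inversion step is needed; an explicit invert flag
exists as an escape hatch.

## Synthetic data

The generator produces before/after pairs with exact ground truth. What it
emulates:

* **Polished surfaces**: uniform bright field (0.66) with thin, slightly
  blurred bright/dark scratch chords; with no scratches and no noise the
  surface is exactly constant.
* **SLA surfaces**: multi-octave value noise weighted toward fine scales
  (grain texture of an acid-etched surface is 1–5 µm at 250 nm/px), sparse
  pit-like dark minima, and a near-planar illumination field whose
  amplitude parameter is its maximum deviation (default 0.15). The
  illumination is applied to the composed scene — shading affects biofilm
  and surface alike — and is low-order by design, since the protocol's own
  background subtraction can only correct low-curvature fields.
* **Biofilm**: chains of overlapping discs (coccus radius 3 px ≈ 0.75 µm,
  center spacing 1.6 radii, random-walk orientation) grouped into compact
  microcolonies (12–26 chains around a common center); small inter-cell
  crevices are closed, standing in for the extracellular matrix of a dense
  mat. Rendering gives every cell a bright ring at its radius (the SEM
  edge effect), a slightly darker core, and an extra boost on the outer
  colony boundary. Body intensity is anchored near the SLA surface mean,
  so fill contrast is weak on SLA — a global threshold fails there — while
  the brighter polished background provides the clear contrast seen on
  smooth surfaces.
* **Treatment**: removal deletes whole clusters (mechanical disruption
  detaches biofilm in patches). A fixed random permutation of cluster ids
  makes the removed set nested in the removal fraction, so the realized
  percent remaining is monotone in it. The after frame is re-rendered on
  the same surface with fresh noise, then rigidly misaligned by a
  configurable (θ, tx, ty).

Coverage is grown to slightly below target before crevice closing tops it
up; realized coverage lands within ±0.01 of target at default settings
(the contract allows ±0.05). Identical spec and seed give bit-identical
pairs; all randomness derives from named child streams of the seed.

What it does **not** emulate: Poisson shot noise (noise is additive
Gaussian after rendering), charging and beam astigmatism, rod-shaped or
mixed-species morphology, partial biofilm detachment within a cluster, and
any EPS texture beyond gap-filling. Passing tests therefore show that the
pipeline recovers truth under controlled contrast, texture and alignment
conditions; they do not certify accuracy on real micrographs, where
appearance variability is larger and reference masks are human-drawn.

## Validation harness

* **Confusion metrics**: pixel-wise sensitivity `TP/(TP+FN)` and
  specificity `TN/(TN+FP)` with biofilm positive; undefined ratios are
  reported as NaN with a warning, never silently zero.
* **ROC scatter**: one (1−specificity, sensitivity) operating point per
  image — a per-image scatter, not a threshold sweep. (A probability
  threshold sweep is available from the probability map but is a separate,
  clearly non-protocol output.)
* **Reproducibility experiment**: on one image, a reference classifier is
  trained from 40 randomly placed class-valid ROIs and its cleaned
  segmentation becomes the reference; six repeats are trained with fresh
  random ROI counts in [10, 20] and fresh placements, and each repeat is
  scored against the reference. ROI placement is rejection sampling — a
  candidate square is accepted for a class only if ≥ 90% of its
  truth-mask pixels are that class — stratified over a shuffled 3×3 grid
  of sectors, emulating an operator spreading unambiguous samples across
  the image. The experiment is fully deterministic for a fixed master
  seed. Note the deliberate omission: the interactive protocol lets the
  operator reposition ROIs and retrain when a segmentation looks poor;
  the harness never does, so occasional low-ROI repeats carry the full
  small-sample variance of one-shot training.
* **Rank-sum test**: two-sided Mann–Whitney with midrank ties. With
  combined n ≤ 12 and no ties the p-value is exact, from the classic
  recurrence for the null distribution of U; otherwise the normal
  approximation with tie and continuity corrections is used. The switch
  point and branch are recorded in the output.

## Known limitations

* Percent remaining inherits the false-positive floor of segmentation:
  when almost no biofilm remains, the ratio is dominated by residual
  false-positive area. The pairwise contrast mapping removes the dominant
  source of this error in the pipeline, but fields with very few bacteria
  remain the least reliable case.
* ROI-label (operator) training without iteration is measurably weaker
  than truth-guided training; real use assumes the operator inspects the
  overlay and re-runs training with edited ROIs when needed.
* The registration contract assumes pairs, always mapping after onto
  before; image stacks are out of scope.
* Runtime scales with image area and feature count; the experiments in
  the test-suite use 128–512 px square images (a 512×512 default-feature
  stack takes a few tens of seconds on one CPU), which keeps the complete
  suite and the acceptance run within ordinary CI budgets.
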