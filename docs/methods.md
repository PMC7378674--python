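# Methods

## Pipeline model

The screening chain treats a single axial CT slice as a 2-D intensity
grid on [0, 255] and makes three simplifying assumptions:

* **Hyperdensity is the signal.** Everything the classifier sees is
  the white-pixel pattern after global thresholding; tissue texture,
  Hounsfield calibration and contrast agents are outside the model.
  A lesion is detectable only insofar as its pixels exceed the
  threshold while normal parenchyma does not.
* **Geometry is summarized by zones.** The 8 × 8 zoning grid reduces
  a 512 × 512 binary image to 64 counts. Max-normalization
  (Z_n / Z_highest) makes the features scale-free: multiplying all
  counts by a constant changes nothing, so the classifier responds to
  the *spatial distribution* of white mass, not its absolute amount.
* **Two classes, one prototype each.** LVQ1 with a single prototype
  per class can only carve the feature space into two half-spaces
  (locally, a nearest-mean rule). That is adequate for the
  lesion-present / lesion-absent contrast the features encode, and it
  keeps training deterministic and inspectable.

### Threshold

`ThresholdSpec` defaults to the fixed intensity 128, the operating
point used for CT screening; `mode="midpoint"` computes
T = (f_max + f_min)/2 per image instead. Equality maps to black — the
comparison is strictly greater-than — because the source rules define
only the two strict cases; the tie side is a convention and is pinned
by tests. RGB conversion is the unweighted channel mean rounded
half-up (no luminance weighting: CT exports are gray in all channels,
so the choice only matters for pathological inputs).

### Zoning

Zones are equal rectangles; the image must divide evenly by the grid
(a 512 × 512 image on the default 8 × 8 grid gives 64 × 64-pixel
zones). Indexing is row-major and 1-based: zone n = (row−1)·8 + col.
An all-black binarized image has no defined features; the package
raises `DegenerateImageError` rather than emitting NaNs, and the CLI
logs and skips such files. Argmax ties break to the lowest zone
index, which makes every downstream result deterministic.

### Localization

Localization is *derived* plumbing, not a learned output: for a slice
predicted suspected, the argmax is restricted to interior zones (rows
and columns 2..7 on the default grid, `interior_margin=1`) because the
skull ring otherwise dominates, and the winning zone's column decides
the side — left iff column ≤ cols/2, in the image-display convention.
The radiological patient-side convention (image left = patient right)
is deliberately not applied; flip the reported side if patient-side
labels are needed.

### LVQ training

Defaults: `alpha=0.05`, `dec_alpha=0.9`, `max_epoch=100`, `eps=1e-4`
(α floor). These are conventional LVQ1 values — a small initial rate
with geometric decay gives a total step budget of α/(1−dec_α) ≈ 0.5,
enough to move a prototype across the unit-box feature space without
oscillation; training on separable phantom cohorts converges to zero
mismatches in well under the epoch cap. `eps` is interpreted as the
learning-rate floor (training stops once α ≤ eps): the stopping
quantity named "minimum error" in classical descriptions is coupled to
the decaying rate, and the rate floor is the reading that terminates.
Initialization consumes the first training sample of each class as
that class's prototype and removes it from the iteration set (classic
LVQ bootstrapping); with a fixed sample order the whole procedure is
RNG-free, and `train` returns a new model, leaving its input intact.
The repulsion update for a wrong-class winner (w ← w − α(x − w)) is
the standard LVQ1 counterpart of the attraction rule; descriptions
that print only the matched case are extended with it so every sample
updates exactly one prototype.

A note on tabulated reference values: the published per-image test
table for this operating point reports two distances per image
("Weight 1 / Weight 2"); our `predict` returns the same per-class
distance pair. The published *training* table's single "Weight" column
has no stated definition and is not reproduced; the training log
(epoch, α, mismatch count) is exposed instead.

### Evaluation

The positive class is *suspected*. Sensitivity is TP/(TP+FN) and
specificity TN/(TN+FP); an occasionally-printed TP/(TP+TN) variant is
inconsistent with the tabulated 90% = 9/(9+1) at the reference
operating point and is not used. Metrics with a zero denominator are
reported as `None` ("n/a" in the CLI), never NaN. ROC analysis here
is a single operating point — a nearest-prototype decision has no
threshold to sweep — so the report emits one (FPR, TPR) pair, not a
curve.

## Synthetic phantoms

`generate_phantom` renders what the pipeline actually consumes:

| parameter | default | rationale |
|---|---|---|
| size | 512 px | the standard CT export size the zoning grid assumes |
| skull ellipse | outer (0.461, 0.441)·size; inner (0.445, 0.426)·size | see below |
| skull intensity | 230 | well above threshold: always white |
| interior intensity | 90 | well below threshold: black at ~4.8 SD of noise |
| lesion intensity | 200 | hyperdense but sub-cranial, white after thresholding |
| lesion radius | 20 px | ~1250 white px, comfortably dominating its 64×64 zone |
| noise SD | 8 intensity units | moderate acquisition noise; spurious white pixels ≈ 10⁻⁶ per pixel |

The skull semi-axes were fixed by a design computation, before any
end-to-end run: an elliptical ring inevitably crosses from the border
zones into the four interior corner zones, so the ring was thinned
(≈ 8 px) until its largest interior-zone count (~670 px at size 512)
sits below the white area of the smallest jittered lesion (~900 px at
radius 17). This guarantees the interior argmax is the lesion zone —
exactly recoverable at zero noise — rather than a skull fragment.

`generate_cohort` jitters suspected phantoms per image: lesion zone
drawn uniformly from the interior zones that can hold the disc inside
the inner skull ellipse, radius ±3 px, intensity ±15 (floored at 140),
sub-zone center offset ±8 px per axis. The default jitter keeps the
disc inside its zone (max per-axis reach 23 + 8 = 31 px < the 32-px
zone half-width), which is what makes the seeded zone the ground truth
for localization. Noise is additive Gaussian, then clipped to
[0, 255] and rounded; clipping is simpler than truncated sampling and
its bias is irrelevant at 4+ SD from both thresholds. All randomness
flows from a single `numpy` generator seeded by the caller, so cohorts
are bit-reproducible; changing the seed changes pixels and lesion
placements but never label counts.

### What the phantoms do and do not show

The phantoms reproduce the *mechanics* the pipeline relies on — a
bright cranial ring, a dark interior, a compact hyperdense focus —
and the cohorts are linearly well separated in zone-feature space, so
a converged classifier scores them at or near 100%. They do not
reproduce partial-volume effects, anatomically varied skulls,
isodense or diffuse lesions, beam-hardening artifacts, or inter-scanner
intensity shifts. Passing the synthetic acceptance checks therefore
demonstrates that the implementation is correct and internally
consistent, not that the method reaches any particular accuracy on
clinical images; reported clinical-style figures (e.g. 85% on a 20-image
hospital test set) are not reproducible without that data.

## Problem sizes

The test suite and `scripts/acceptance.py` use 512 × 512 phantoms in
cohorts of 10 + 10 per split, five independent train/test replicates
(200 images end-to-end), plus a 10-phantom noiseless localization
check — the scale at which the study design is stated, and enough for
the aggregate metrics to be stable across seeds.

## Known limitations

* One prototype per class cannot express multimodal classes
  (LVQ2/LVQ3 and multi-prototype variants are out of scope).
* The global threshold is not adaptive; slices whose parenchyma
  straddles 128 would binarize badly (midpoint mode helps only if the
  extremes are representative).
* Localization names one dominant zone; multifocal disease is reported
  as its single largest focus.
* The DICOM reader is a min-max rescale convenience, not a calibrated
  Hounsfield window.
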