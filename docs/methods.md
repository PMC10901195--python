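# Methods

This note documents the models, parameters, numerical choices and known
limitations of `mousetrack`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the code does not measure.

## Imaging regime and assumptions

The pipeline targets top-down recordings of a small, fixed arena under
controlled (infrared) illumination: dark animals on a bright, diffusely
lit floor, a fixed camera, constant brightness over the session. The
reference geometry is a 540 × 540 px image of a 30 × 30 cm arena at
30 frames/s, i.e. ≈18 px/cm; all pixel defaults below are stated at that
scale and should be scaled linearly for other image sizes
(`mousetrack.benchmark.scaled_arena` does this).

Two structural assumptions are load-bearing:

* **Contrast**: every animal pixel is darker than half the local
  background intensity. The conventional segmentation stage depends on
  it; when it does not hold the stage can be disabled
  (`use_conventional: false`) and every frame goes to the
  instance-segmentation backend.
* **Continuity**: animals move a small fraction of their body length per
  frame. Identity stitching by mask overlap has no motion model and no
  appearance model; it is only correct when consecutive masks of the
  same animal overlap more than masks of different animals.

## Pipeline stages

### Background model and foreground extraction

`build_background` supports a pre-experiment model (pixel-wise mean of
empty-arena frames) and a temporal median over the first `k` frames
(default k = 300, i.e. 10 s at 30 fps). The median variant assumes each
pixel is animal-free in more than half of those frames; an animal that
loiters in one spot for most of the window is absorbed into the
background and its foreground silhouette erodes. The synthetic protocol
therefore uses the pre-experiment model, which the generator can render
exactly (`render_empty_arena`). Real deployments that lack empty-arena
footage should check the median window against the animals' mobility.

Foreground is thresholded per pixel at 0.5 × background, then cleaned by
binary closing with a 9-px-radius disk followed by opening with a
3-px-radius disk. The morphology is implemented with Euclidean distance
transforms (a pixel is within the dilation iff its distance to the
foreground is ≤ r), which is exactly equivalent to disk-structuring-
element morphology — the unit tests assert bit-equality against
scikit-image — but much faster at these radii; computation is windowed
to the foreground bounding box. Components with fewer than
`min_component_area` = 200 px² (at 540 px; scaled quadratically) are
discarded: mouse-sized blobs at this resolution are several thousand
pixels, bedding speckle far smaller. Frames whose component count equals
`n_animals` bypass the backend ("pass-through").

### Failure filter and gap-fill

Backend detections are reduced to the `n_animals` most confident (ties
by area). A frame fails when fewer remain, when any kept confidence is
below `conf_min` = 0.9, or when any kept area is below
`area_frac_min` = 0.2 of the largest kept area. Both bounds are strict
inequalities: confidence exactly 0.9 and area exactly 20% pass. Failed
frames receive copies of the temporally closest successful frame's
masks; equidistant ties resolve to the earlier frame (causal
preference). The fraction of failed frames is reported per run as
`failure_fraction`.

### Identity stitching

For two animals the per-frame rule is, with `prev_i` the mask identity
`i` held on the previous frame and `M1, M2` the current masks:

```
δ1 = IoU(prev_1, M1) − IoU(prev_1, M2)
δ2 = IoU(prev_2, M1) − IoU(prev_2, M2)
if |δ1| > |δ2|:  δ1 > 0 → (M1, M2)  else (M2, M1)
else:            δ2 > 0 → (M2, M1)  else (M1, M2)
```

The final branch is the fixed tie-break when neither previous mask
overlaps anything (e.g. after a long gap-fill): input order is kept.
Whenever the deciding δ is nonzero and δ1 ≠ δ2, this rule provably picks
the permutation with the larger total IoU; the property suite verifies
the equivalence on thousands of random mask pairs. Frame 1 is
initialised deterministically: identity 0 is the mask with the smaller
centroid x (ties by y). For more than two animals the total-IoU-optimal
permutation (Hungarian assignment) is used instead. IoU is computed on
full-resolution masks.

### Mask-based keypoint detection (MD)

Per mask, the principal length is the maximal pairwise distance between
contour pixels, computed on the convex hull of the boundary (the hull
contains the diameter endpoints; the brute-force pair search over hull
vertices is exact). The detector is two-pass: pass 1 computes each
animal's median principal length over the whole video (a per-animal,
whole-video median — not a running one); pass 2 labels frames.

A frame is *parallel to the floor* iff its length strictly exceeds the
median **and** the mask lies entirely inside the floor region (default:
the frame eroded by 10 px at 540-px scale; configurable polygon). On
parallel frames the snout is the endpoint whose three terminal tenths of
the width profile (mask extent perpendicular to the endpoint axis, 10
equal bins) have the smaller mean — the mouse's rear is wider than its
head. This taper rule is this package's own disambiguation choice; other
implementations of the same idea may use different parallel-frame rules.
On non-parallel frames (rearing, curled, against a wall) the endpoints
inherit labels from the previous frame by the total-distance-minimising
2 × 2 pairing; frames before the first parallel frame are labelled by
backward propagation. A video in which an animal never produces a
parallel frame is a hard error with a diagnostic — the median-length
criterion is meaningless if the animal rears or curls most of the time,
and that failure should be loud, not silent.

### Conditional ensemble

External per-frame keypoints (native CSV or the multi-row-header
pose-table dialect emitted by common multi-animal pose estimators) are
first mapped to internal identities by mask containment: an external
track belongs to the identity whose masks contain the majority of its
valid points over the video; ambiguous or colliding mappings are errors.
The per-frame rule is binary: external snout and tail-base are both
valid and both inside that identity's *own* mask → take the external
coordinates; otherwise keep MD. Own-mask (not any-mask) containment is
deliberate: the rule exists to reject cross-animal swaps, and a swapped
point lies inside the *other* animal's mask. Containment is tested on
the nearest pixel; boundary pixels count as inside. There is no
distance-based soft fallback.

### Behavior scoring

Sniffing, per frame and ordered (actor, recipient) pair, with threshold
t = `sniff_threshold_px` (default 25 px at 540-px scale ≈ 1.4 cm):
head-directed if the actor's snout is within t of the recipient's
snout; else anogenital-directed if within t of the recipient's
tail-base; else body-directed if within t of the recipient's mask
(exact point-to-pixel-set distance); else none. The precedence
(head > anogenital > body) makes the label single-valued: a snout near
the recipient's snout is necessarily near its mask too.

Touching, per unordered pair: shortest mask-to-mask distance below
`touch_threshold_px` **and** no sniffing label in either direction that
frame — i.e. contact that is not snout-directed investigation. The
touching threshold (default 25 px) and the stationary-speed criterion
(default 15 px/s ≈ 0.8 cm/s) are package defaults exposed in the
config; treat them as starting points to calibrate per arena.

Events are maximal same-label runs with no minimum duration and no gap
merging by default (`--min-event-frames`, `--merge-gap-frames` expose
both). Duration = run length / fps; inter-event interval = gap between
consecutive events of the same behavior. Locomotion uses the center
point (midpoint of snout and tail-base): total path length, stationary
time (instantaneous speed below threshold), velocity in 1-s bins, and
the Pearson correlation between the two animals' binned velocities.
The frame-level benchmark helper scores one label sequence against a
reference as per-behavior precision/recall/F1 (F1 = harmonic mean).

### Evaluation

* **PCKh**: fraction of keypoints within a fixed pixel threshold of the
  annotation, over valid ground-truth entries. The threshold represents
  half the average head length; the default of 15 px at 540-px scale
  (≈0.8 cm) is the package's calibration for adult mice at 18 px/cm.
* **MOTA** `= 1 − Σ(mₙ + fpₙ + mmeₙ) / Σ gₙ` with CLEAR-MOT matching:
  previous-frame matches are kept while within the threshold, remaining
  targets are matched by distance-minimising assignment (forbidden
  beyond the threshold), and a matched ground-truth target whose track
  changes counts one mismatch. Snout, tail-base and center are scored
  as independent target types. The matcher is verified against an
  exhaustive enumeration oracle on hundreds of random small scenarios.
  The match threshold defaults to the PCKh threshold so "missed" and
  "incorrect" agree across metrics.
* **Identity switches**: frames at which the center-point
  correspondence between predictions and ground truth changes.
* **Mask AP**: COCO-style — greedy matching by descending confidence at
  IoU thresholds 0.50:0.05:0.95, all-points (monotone-envelope) PR
  interpolation; AP50/AP75 at the fixed thresholds.
* **Error distributions**: mean/median plus Tukey outliers
  (> P75 + 1.5 · IQR), with count and mean outlier size.

## Synthetic scenes

The generator renders what the pipeline assumes: dark agents
(intensity 40) on a bright floor (intensity 200), so the 0.5 ×
background threshold sits at 100 with ample margin on both sides. Agents
are tapered capsules — a wide rear circle (r = 22 px at 540-px scale)
and a narrow front circle (r = 9 px) swept along the 70-px body axis —
giving an unambiguous true snout at the narrow tip and a rear-to-front
width taper matching the MD assumption. Motion is a correlated random
walk (speed 3 px/frame ≈ 5 cm/s, heading diffusion σ = 0.15 rad/frame)
with two physicality constraints: walls are handled by rate-limited
steering away (≤ 0.3 rad/frame), never by instantaneous reflection, so
the body orientation — and hence the true snout — cannot jump between
frames; and bodies are solid, kept from coinciding by a pairwise
minimum axis-to-axis distance of half the rear radius, which still
allows the partial overlap of real contact (crawling over) but forbids
the near-total interpenetration that would make identity genuinely
unrecoverable from overlap alone. Scheduled episodes force interaction
structure: *approach* steers one agent toward the other, *contact*
brings both together until their masks overlap and holds, *cross*
makes the agents swap sides so their paths intersect.

Artifacts mimic common clutter: a static bedding speckle texture
(clipped so the contrast invariant survives), a 2-px bright tether line
from one agent's rear to the nearest wall, and a bright headstage disc
over the head that locally destroys contrast (exercising the
failure-filter and gap-fill paths). External-estimator corruption
applies, per frame and keypoint type, cross-animal swaps (probability
q), Gaussian jitter (σ), and per-point dropout (p).

All randomness derives from the scene seed through named substreams;
identical configurations are bit-identical. Ground-truth behavior
labels are produced by running the package's own classifier on the
ground-truth geometry, which makes generator/classifier consistency a
testable invariant rather than an assumption.

**What the generator does not emulate**: body deformation (the agents
are rigid capsules), fur texture, shadows, grooming/rearing postures
(rearing is exercised in unit tests by substituting shortened masks,
not by the motion model), fighting or mounting, and illumination drift.
Passing the synthetic protocol therefore demonstrates the correctness
of the algorithms under the stated assumptions — not performance on any
real recording.

## The evaluation protocol (`mousetrack.benchmark`)

The standing protocol is 50 videos × 500 frames at 30 fps with an
approach (frames 10–20%), contact (20–32%), crossing (50–60%) and a
second contact (70–82%) episode, run end to end: conventional
segmentation with the pre-experiment background, oracle backend on
non-pass-through frames, failure filter, gap-fill, IoU stitching, MD
keypoints, and the conditional ensemble against an external set
corrupted with p = 0.05 dropout, q = 0.02 swaps and σ = 3 px jitter.
Scenes are rendered at 256 × 256 px with all lengths scaled from the
540-px reference geometry — a resolution choice made so the whole
protocol runs in a few minutes on one CPU while preserving every
geometric relation; thresholds scale with it.

Reported quantities: total identity switches, pooled MOTA per target
type, PCKh, mean errors of MD / ensemble / external keypoints,
snout-label accuracy outside interaction episodes, the fraction of
keypoints lying on the assigned mask contour, and outlier counts. For
the ensemble-vs-external outlier comparison the Tukey fence is computed
on the *external* (baseline) distribution and applied to both error
pools: the question the comparison answers is whether the ensemble
removes the baseline's gross errors, and a per-pool fence would
paradoxically penalise the method with the tighter bulk (its own fence
drops so low that mild errors count as outliers). Per-pool summaries
are reported alongside.

## Known limitations

* Identity stitching has no appearance model: if both animals are
  entirely replaced by gap-fill for a long stretch while they move, the
  post-gap assignment is overlap-based guesswork, as it is in any
  overlap stitcher.
* The median-length posture test degrades when an animal spends most of
  a video rearing or curled; the error message says so explicitly.
* The temporal-median background assumes per-pixel majority vacancy
  over the window (see above).
* The CNN backend is an interface (`SegmentationBackend`) plus an
  oracle implementation; no trained segmentation model ships with the
  package, and mask AP is provided to evaluate whichever backend the
  user plugs in.
* Behavior scoring covers distance-threshold sniffing, touching and
  locomotion only; fighting and mating involve occlusion patterns
  outside this method's assumptions.
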