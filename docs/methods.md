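# Methods

## Problem setting

Detection-based plant-disease diagnosis produces, for each greenhouse
image, a set of scored, class-labeled bounding boxes.  Two structural
problems limit single-stage detectors on this kind of data: heavy class
unbalance (in the tomato benchmark this package models, leaf mold has
~24% of all annotated boxes and powdery mildew ~0.7%) and a substantial
false-positive rate driven by inter-/intra-class appearance variation
(roughly 10% of emitted boxes at IoU 0.5).  `refinebank` implements the
refinement-filter-bank strategy for this regime: leave the detector's
recall R = TP/(TP+FN) as it is, and raise precision P = TP/(TP+FP) by
passing every detection through a per-class binary verifier and deleting
the ones judged False.

## Evaluation protocol

Boxes are axis-aligned with half-open pixel intervals, so
area = (x_max − x_min)(y_max − y_min) is exact and IoU arithmetic has no
±1 ambiguity.  Pascal VOC XML (1-based, inclusive) is converted on read:
x_min_internal = xmin_voc − 1, x_max_internal = xmax_voc.

Matching is the Pascal VOC greedy protocol: detections in descending
score; each matches the highest-IoU *unmatched* same-class ground-truth
box of its image; a match requires IoU ≥ threshold (configurable to
strict >, the ≥ convention keeps threshold 1.0 satisfiable by exact
matches); every ground-truth box is claimed at most once, so duplicates
are false positives.  Score ties keep input order and IoU ties take the
lowest ground-truth index, making the whole pipeline deterministic.
A consequence used by the refinement claim: false positives never claim
a ground-truth box, so deleting any subset of FP-status detections
leaves every remaining status unchanged, and per-class AP cannot
decrease.  This is asserted as a property test and is the mathematical
basis of the filter-bank approach.

Average precision is the 11-point interpolated form: AP = (1/11) Σ
P_interp(r) over r ∈ {0, 0.1, …, 1.0} with P_interp(r) = max precision at
recall ≥ r.  mAP averages classes with at least one ground-truth box;
classes with zero ground truth are excluded (not scored 0) and reported,
which avoids penalising absent rare classes in small synthetic runs.
True negatives are undefined for open-background detection and are
reported as not-applicable.

## Primary-detector simulator

Training a region-proposal detector is out of scope; the primary unit is
a pluggable contract plus a calibrated simulator.  Per ground-truth box:
dropped with probability `miss_rate` (default 0.05); edges jittered with
Gaussian sd `loc_jitter_sd` (default 2 px); the emitted label drawn from
a row-stochastic confusion matrix (defaults leak 5% along the observed
confusable pairs canker→plague, gray mold→canker, low temperature→
canker); score from a truncated Gaussian (TP mean 0.85, sd 0.1).  Per
image, Poisson(`fp_rate`) spurious boxes with uniform centres,
log-uniform sides in [16 px, image/2] and scores around 0.55 emulate
background false alarms.  `fp_rate` is calibrated in closed form so the
expected FP share (mislabeled + spurious) matches the benchmark's
published 10.03% operating point: with g = (1−miss)·boxes_per_image
emissions of which fraction m are mislabeled, s = g(t−m)/(1−t).

## Filter bank

One independent CNN per class ("adding a class adds exactly one
verifier").  Patches are extracted without resampling, then scale-adapted:
boxes with longest side ≤ `side_cutoff` (150 px at production sizes) go
to the small square, the rest to the large square (defaults 300²/500²;
test suites use 64²/96² — the adaptation semantics are unchanged, only
the raster sizes).  Routing by the longest source-box side is our
reading of the two-scale adaptation; each box is fed at one scale.

The verifier architecture is `conv_depth` ∈ 1..5 blocks of [3×3 conv,
ReLU, 2×2 max-pool] with widths 16·2^(layer−1) capped at 128, followed
by three fully-connected layers (256, 64, 2-way softmax).  The reference
design uses 5 conv + 3 FC layers; the depth variants exist for the
capacity study.  Training is cross-entropy with Adam (lr 1e-3, batch 32)
under a cosine learning-rate decay to ~0, so the final weights are a
settled state rather than a mid-oscillation snapshot; everything is
float32 numpy (im2col convolutions) and fully deterministic given the
seed.  Non-finite losses abort with a diagnostic.

Training sets per class: positives are the class's true-positive
detection patches; negatives are the false positives the detector
assigned to that class plus background patches (healthy tissue/scene
clutter sampled with IoU ≤ 0.2 against every annotation) drawn to top
negatives up to a 1:1 balance — the hard-negative construction that
counteracts class unbalance in the secondary stage.  The split is
stratified 80/20 by default.  A class with no true positives cannot be
trained; the bank then passes its detections through unjudged, with a
warning (silently deleting a whole class's detections would be worse
than not filtering them).

The decision rule is probability ≥ 0.5 (configurable threshold).  The
integration unit keeps True verdicts and drops False ones; it never
relabels, re-scores or re-localises a detection, and reports recall
retention (after-TP / before-TP) next to the precision gain so the
fix-recall-improve-precision intent is measurable.

A note on weight sharing: descriptions of this architecture sometimes
suggest the two stages share convolution weights while also calling
every bank CNN an independent network.  The two statements cannot both
hold operationally; this implementation trains the stages consecutively
(detector output first, then the bank) with no parameter sharing.

## Synthetic scenes

The generator emulates the statistical structure of the real benchmark,
not its appearance: a smooth foliage-like background; Poisson(6) lesions
per 512² scene, each an inscribed ellipse of a class-specific
colour/spot texture with box sides 32–160 px and pairwise overlap
(intersection over smaller box) ≤ 0.5; class frequencies equal to the
benchmark's annotation shares renormalised over the ten disease classes;
and near-identical texture recipes for the confusable pairs
(gray mold ≈ canker ≈ plague), so verifiers face a genuinely hard
discrimination.  Scenes, annotations and splits are byte-identical
across runs with the same seed.  The standard augmentation transforms
(resize, crop, rotation, horizontal flip, contrast, brightness, colour,
noise) move boxes consistently with pixels; rotation maps boxes to the
axis-aligned bound of their rotated corners and crops drop boxes
retaining under 25% of their area.

What the scenes do *not* model: photorealistic lesion morphology,
illumination and camera variation, occlusion, multiple pathologies per
region.  Passing benchmarks here demonstrates the pipeline's
correctness and the refinement mechanism under a controlled ~10%-FP
regime — not field performance on real crops.

## Reference benchmark conditions

The end-to-end benchmark uses 200 scenes at 512², the calibrated
detector (≈1,250 detections, ~10% FP), verifier input 64², depth 5,
12 epochs, seed 1234.  These desk-scale sizes keep a full run on one CPU
core in minutes.  Under these conditions refinement raises
micro-averaged precision by several points (≈0.91 → ≈0.99) while
retaining >99% of true positives, and an oracle verifier (probability 1
on TPs, 0 otherwise) yields precision exactly 1.0 — the upper bound of
the mechanism.

## Depth study

The capacity study retrains one verifier per conv depth 1..5 on a
confusable-pair patch fixture (canker vs plague textures) and records
the held-out loss.  Two design points matter.  First, the fixture must
sit in the partial-learning regime: if the pair is trivially separable
every depth saturates and loss differences are margin noise, and if it
is unlearnable every depth sits at chance.  The study therefore renders
32×32 patches with spot density tripled (so a small patch carries
enough texture to discriminate — at the default density a 32² patch
holds under one spot) and appearance noise scaled ×1.3, with only 160
training patches, a size at which shallow verifiers visibly overfit.
Second, a single training run's final loss carries optimisation noise
of the same order as adjacent-depth differences, so each depth is
trained five times from distinct seeds and the replicate-mean final
loss is compared.  Under this protocol the mean loss decreases
monotonically from depth 1 to depth 5, matching the observation that
5-layer verifiers are the stable choice while 1–2-layer ones fail to
generalise.

## Numerical and degenerate-input choices

Interpolated precision uses a 1e-12 recall tolerance so r = k/10 levels
are not missed to float rounding.  Empty ground truth makes every
detection FP (not an error); zero-GT curves are empty and their AP is 0.
Degenerate jittered boxes are resampled up to 10× then skipped with a
warning; unplaceable scene boxes likewise after 100 attempts.  Detection
CSV stores coordinates at 2 decimals (the simulator's sub-pixel jitter
does not survive serialisation exactly; round-tripping already-rounded
values is exact).  Background sampling retries up to 50× per requested
box and warns if the quota is not met.

## Known limitations

The verifier engine is a minimal CNN stack (no batch norm, no
augmentation at train time, no pretrained features); it is adequate for
the synthetic textures but would need a stronger backbone for real
imagery.  The simulator draws spurious-box labels uniformly rather than
from the per-class FP profile.  mAP on the synthetic benchmark is not
comparable to published real-data numbers — the arithmetic checks on the
published per-class tables are the only bridge to those values.
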