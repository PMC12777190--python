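# Methods

## Problem and scope

`aacscore` implements an automated pipeline for abdominal aortic
calcification scoring (AACS) on lateral lumbar radiographs following the
Kauppila protocol. The pipeline has four stages: (1) decoding the 20
vertebral corner landmarks (L1–L5, four corners each) from dense
center-heatmap / offset maps; (2) constructing the four abdominal aortic
segments (AAS) anterior to L1–L4 from those landmarks; (3) scoring each
segment crop with a small convolutional regressor trained with a
contrastive rank-aware loss; and (4) the agreement/classification battery
used to validate automated scores against manual ground truth. Because
clinical radiographs of this kind are private, the package ships a
synthetic phantom generator that produces images with exactly known
landmarks, plaques and scores; every stage is tested against it.

## Kauppila arithmetic

Each aortic wall (anterior, posterior) at each lumbar level L1–L4 is
graded 0–3 by the calcified fraction f of the segment length: 0 if f = 0,
1 if f < 1/3, 2 if 1/3 ≤ f ≤ 2/3, 3 if f > 2/3. The per-segment score is
the sum of the two wall grades (0–6); the total AACS sums the four
segments (0–24) and is binned into no/mild (≤ 4), moderate (4 < t ≤ 15)
and severe (> 15). Grading at exactly 1/3 or 2/3 is resolved to the
middle interval (grade 2): the fraction thresholds are inherently visual
in clinical use and no tie rule is standard, so we read "1/3 to 2/3" as
inclusive. The synthetic generator keeps a 0.02 margin away from interval
endpoints so that rasterization can never flip a grade. Coverage of
multiple disjoint plaques on one wall is summed, since fraction-of-length
coverage is additive for non-overlapping plaques.

## Landmark decoding

Only the output contract of the landmark detector is implemented: a
center heatmap at 1/stride resolution with one Gaussian peak per
vertebral centroid, a 2-channel sub-stride center offset, and an
8-channel corner offset (corner minus centroid, in image pixels).
Decoding uses 3×3-neighborhood local-maximum non-maximum suppression with
a score floor of 0.1, takes the top-k peaks by score (ties broken by
smaller row, then column), reconstructs centers as
`(cell + offset) × stride`, adds the corner offsets, and labels vertebrae
L1..L5 by increasing center y. The peak Gaussian (σ = 2 cells) is
centered on the integer cell containing the downsampled centroid, so the
render → decode round trip recovers corners to float precision; the
acceptance suite checks < 0.5 px over 50 phantoms. Keypoint error is the
Euclidean distance per landmark, averaged over the 20 corners, reported
in pixels and in mm via the pixel spacing (default 0.1343 mm/px, so an
18.47 px error corresponds to 2.48 mm).

## Aortic segment geometry

Boundary 0 joins L1's two upper corners (a deliberate substitute for the
often-truncated T12 interface). Boundary i (i = 1..4) joins, per side,
the midpoint between the lower corner of L_i and the upper corner of
L_{i+1}; this uses exactly the annotated corners and degenerates
gracefully when vertebrae touch. Each boundary is oriented
posterior → anterior using the configured `anterior_side` (the side of
the image the abdomen faces; never inferred from pixel content) and then
extended past its anterior endpoint by its own length. Segment L_i is the
quadrilateral between the anterior endpoints and tips of boundaries
i−1 and i, i.e. the paravertebral band anterior to the spine, excluding
the vertebral body. The four quadrilaterals tile without overlap and the
whole construction is rigid-motion equivariant (tested to 1e-6 px).
Crops are taken from the polygon's axis-aligned bounding box intersected
with the frame, with out-of-polygon pixels zeroed, and resampled
bilinearly to a fixed size — no rotated rectification, which keeps the
contract deterministic and trivially invertible in tests.

A vertical boundary (both endpoints at the same x) is rejected, because
left/right anteriority is undefined for it; in practice this only occurs
for pathological landmark sets.

## Contrastive rank-aware loss

For segment feature vectors F_i with integer scores v_i, anchor i and
positive j define the negative set
S_ij = {k ≠ i : |v_i − v_k| > |v_i − v_j|}. Each ordered pair contributes
an InfoNCE-style term with cosine similarity and temperature τ over the
candidate set {j} ∪ S_ij, and the loss averages over anchors and
positives. The candidate set of the softmax is fixed to {positive} ∪
negatives — the standard InfoNCE convention — because the pairing
narrative (farther-ranked samples act as negatives for a given positive)
requires the denominator to depend on the pair. A pair with no negatives
contributes exactly 0 (denominator equals numerator), which keeps the
estimator defined for homogeneous batches and makes the loss identically
zero at N = 2. τ defaults to 0.1 (a common InfoNCE choice; no published
value exists for this loss) and the rank term is weighted by
`lambda_rank` (default 1.0) against the MAE regression loss. The
vectorized implementation and its analytic gradient are verified against
a triple-loop brute force (1e-8 over 100 random batches) and central
finite differences.

## Scoring model

The backbone is a small convolutional network written in numpy with
manual backpropagation: three 3×3 conv blocks (8, 16, 32 channels) with
ReLU and 2×2 average pooling, global average pooling, a 64-dimensional
linear feature head (the input to the rank loss) and a scalar score head.
Optimization is Adam with the step-decay schedule
`lr = base_lr × factor^floor(epoch / decay_every)` (defaults 0.001, 0.5,
50). Training augmentations are horizontal flips and brightness/contrast
jitter; a horizontal flip of a segment crop swaps the anterior and
posterior walls, which leaves the per-segment score (their sum)
unchanged, so flipping at crop level is label-preserving. Raw per-segment
predictions are rounded half-away-from-zero and clamped to [0, 6]; the
four rounded scores sum to the total, which is binned into severity.

Three variants share the backbone, seed and schedule for ablation:
`holistic` (whole downsampled frame → total score 0–24, no localization
or segmentation), `segmented` (landmark-driven crops, regression loss
only), and `rank_aware` (crops + the contrastive rank-aware loss). The
estimator follows the scikit-learn protocol (`fit`/`predict`/
`get_params`) and round-trips through `save`/`load` with bit-identical
forward outputs.

Desk-scale defaults — 30 epochs, batch 24, 160 training phantoms with a
40-phantom held-out set — are the problem sizes used throughout the tests
and the acceptance script; they train in about half a minute on one CPU
and comfortably separate the learned model from a constant-median
baseline. The full-scale protocol (200 epochs, ResNet-class backbone,
thousands of radiographs) is out of scope for this package; requesting
`backbone="resnet101"` raises an explicit error since no deep-learning
runtime is a dependency here.

## Synthetic phantoms

A phantom renders five stacked quadrilateral vertebrae (default 60 px
long, 42 px wide, 8 px gaps in a 384×256 frame), globally tilted by a
configurable angle with per-corner Gaussian jitter, a faint aortic band
occupying the middle anteroposterior span of each AAS, and bright plaque
bands hugging one wall of the band. A plaque's coverage fraction along
the segment's superoinferior axis is drawn strictly inside the requested
grade's interval (0.02 margin), so the ground-truth record is exact by
construction and the annotation-oracle scoring path recovers it
identically. Gaussian noise (SD 4 gray levels) is added last.

Two cohort score profiles exist. `uniform` draws the total AACS uniformly
on 0..24 and splits it over the eight walls by sequential
feasibility-uniform draws — this makes every total attainable in modest
cohorts, which independent per-wall sampling would not. `paper_like`
draws wall grades from level-specific categorical distributions chosen so
per-segment medians rise from L1 to L4 and the cohort median total lands
near 8 points, echoing the development-population distribution of the
clinical cohorts this method targets; the generator's own test asserts
the median lies in [6, 10] at n = 500.

What the phantom does not emulate: radiographic photometry (scatter,
bowel gas, soft tissue, vendor-specific contrast), annotation ambiguity,
vertebral deformity, or any correlation between calcification burden and
pose. Passing tests therefore demonstrate correctness of the decoding,
geometry, loss and statistics, and learnability of the synthetic
coverage→score relationship — not clinical-grade accuracy on real
radiographs.

## Agreement battery

All comparisons treat (ground truth, prediction) as two raters of the
same subjects. ICC(2,1) — two-way random effects, absolute agreement,
single measures — is computed from the ANOVA decomposition
`(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))` with the F-based
confidence interval, and is verified against an independent ANOVA
implementation and against `pingouin`. R² is computed on the identity
relationship (residuals pred − gt about the ground-truth mean), matching
its use as an agreement measure rather than a refitted regression.
Bland–Altman reports the mean difference (pred − gt) and bias ± 1.96
sample SD. The paired test is a two-sided Wilcoxon signed-rank with
zero differences dropped and a Bonferroni threshold α/m (0.05/3 ≈ 0.017
for a three-model comparison). TOST equivalence at Δ = ±1 and ±0.5 points
uses two one-sided Wilcoxon tests of the shifted differences — chosen
nonparametric for consistency with the main test — and passing at
Δ = 0.5 implies passing at Δ = 1. Severity classification reports a 3×3
confusion matrix and macro-averaged one-vs-rest SN/SP/PPV/NPV (the
unweighted scheme, since a single value per metric for three classes
does not itself fix the averaging; zero-denominator classes are excluded
with a warning). The boundary distance error of a severity-misclassified
sample is the distance from the predicted total to the nearest integer
score inside the true class's interval, and the mean BDE averages over
misclassified samples only. Reported confidence intervals beyond the
ICC's analytic one use a seeded percentile bootstrap (2000 resamples),
labeled as such.

## Numerical choices and limitations

* Heatmap NMS ties break to the smaller (row, column) cell, making
  decoding invariant to peak discovery order.
* All randomness flows through `numpy.random.default_rng` seeds; cohorts,
  training runs and bootstraps are bit-reproducible per seed.
* Boundary fractions exactly 1/3 and 2/3 compare against the float
  representation of those thresholds, so a value typed as `1/3` grades 2.
* The crop contract resamples the bounding box, not a rectified rotated
  rectangle; on strongly tilted spines crops include more zeroed
  background.
* The localization-error report always uses original-image pixels; no
  resize-dependent rescaling of the error is applied.
* Landmark decoding requires all five peaks above the score floor and
  reports the count found otherwise; partial columns are not scored.
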