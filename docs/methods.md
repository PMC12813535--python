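# Methods

This note documents the models, algorithms and numerical choices behind
`cytoseg`, what the synthetic benchmark does and does not establish, and the
design decisions taken where the design was genuinely open.

## Synthetic image model

Each image is a pale canvas on which cells are painted as pairs of
concentric rotated ellipses: a purple nucleus (default RGB (0.35, 0.20,
0.55)) inside a pink cytoplasm ((0.95, 0.75, 0.80)) on background
(0.97, 0.95, 0.96)), followed by additive zero-mean Gaussian intensity noise
clipped to [0, 1].  The defaults mimic hematoxylin–eosin staining, which
colours nuclei purple and cytoplasm pink; all colours are configurable.

Placement is rejection sampling: nucleus semi-axes, the cytoplasm scale
factor (> 1, so the cytoplasm strictly contains the nucleus), the
orientation (uniform on [0°, 180°), the natural period of an ellipse) and
the centre are drawn uniformly; a placement whose cytoplasm overlaps an
existing cell by more than `max_overlap_fraction` (default 0.3 of the
smaller cell's area) is rejected, with a cap of 100 attempts per cell after
which the image is emitted with fewer cells and a logged warning.  Label
maps store the later-drawn instance in overlap zones (nuclei always win over
cytoplasm overdraw); the full per-instance masks, including shared pixels,
are kept in the ground truth, because partial overlap is precisely what the
watershed and fusion stages must resolve.

No published description of the emulated material's image sizes or
cells-per-image statistics exists, so the defaults (512×512, 2–8 cells;
64×64 with 1–2 cells for the fast benchmark) are the package's own choices.
The generator does **not** simulate staining artifacts, mucus, debris,
out-of-focus blur, or the biological distinction between squamous and
columnar cells.  Consequently, passing the synthetic benchmark shows that
the algorithms are implemented correctly and that the training loop can
recover structure under the stated noise and overlap conditions — it does
not establish clinical-grade accuracy on real smears.

## U-Net and the weighted combined loss

The network is the canonical U-Net: `depth` contracting blocks of two 3×3
convolutions (ReLU) followed by 2×2 max pooling, channels doubling per
stage from `base_channels`; a two-convolution bottleneck; an expansive path
of 2×2 transposed convolutions whose outputs are concatenated with the
matching encoder skip; and a 1×1 output convolution.  Inputs are edge-padded
to a multiple of `2^depth` and the logits cropped back, so output size
always equals input size.  Dropout sits after each encoder block's second
convolution and is disabled at inference.

Training minimises

    L = w_ce · CE_w + w_mse · MSE_w ,   default w_ce = w_mse = 0.5,

where both terms are weighted means over pixels: `CE_w = Σ w(x)·(−log
p_y(x)) / Σ w(x)` and `MSE_w = Σ w(x)·‖p(x) − onehot(y(x))‖² / Σ w(x)`.
The MSE operates on predicted class probabilities against the one-hot
target — the only shape-consistent way to combine a cross-entropy and a
squared-error objective for dense segmentation — and both terms share the
same pixel weight map, so uniformly rescaling all weights leaves the loss
unchanged.  The weight map is `class_weight(class(x))`, multiplied by
`boundary_weight` (default 3) for pixels within `boundary_radius` (default
2, Chebyshev) of an instance boundary; class weights default to inverse
class frequency normalised to mean 1.  This concentrates the loss on the
hard pixels at instance rims.

The optimiser is plain SGD with the L2 penalty added explicitly to weight
(not bias) gradients, and a global gradient-norm clip (default 1.0) that
prevents the large first-step updates which otherwise push most ReLUs dead
on near-constant-colour images.  Full-scale defaults are learning rate
0.001, 50 epochs, batch 16, L2 0.01, dropout 0.5.  Training is fully
deterministic under the run seed (shuffling, dropout and initialisation all
derive from it).

### Small-scale benchmark protocol

All end-to-end tests train a depth-2, 8-channel U-Net on 40 synthetic 64×64
images (1–2 cells each, noise sd 0.02) with learning rate 0.3, batch 8, L2
10⁻⁴, dropout 0.1, and at most 300 SGD steps, then score nucleus Dice on 10
held-out images.  The raised learning rate and reduced regularisation are
the appropriate re-scaling for this problem size; the full-scale defaults
above remain untouched in the config classes.  The benchmark reaches
held-out Dice ≥ 0.97 on the three fixed seeds used in the tests.

## Detector

A deliberately small Mask R-CNN-style pipeline sized for CPU training:

* **Backbone** — a stem convolution plus one stage per pyramid level, each
  `3×3 conv → ReLU → 2×2 max pool`; the **final** stage's convolution uses
  the configured dilation rate (default 2, kernel 3×3).  Dilation enlarges
  the kernel's span to `k + (k−1)(r−1)` pixels without extra parameters and
  is placed in the last stage only, which preserves the stride structure the
  pyramid depends on.
* **FPN** — 1×1 lateral projections to a common width (32), top-down
  nearest-neighbour upsampling with addition, 3×3 smoothing per level;
  levels sit at strides 4, 8, 16, …
* **Anchors** — one square anchor per configured scale per grid position
  per level, clipped to the image.  Anchors with IoU ≥ 0.5 to some ground
  truth are positive, < 0.3 to all are negative, in between ignored; the
  best-IoU anchor per ground truth is always positive.  Training samples all
  positives (capped) and subsamples negatives at random to a 1:3
  positive:negative ratio — the box-level imbalance control.
* **Heads** — a shared 3×3+ReLU head per level feeding 1×1 objectness and
  box-delta convolutions; box regression uses centre/size offsets
  normalised by anchor size with a smooth-L1 loss.  The class-agnostic mask
  head runs on 14×14 bilinear ROI-aligned crops of the finest level and is
  trained on ground-truth boxes (teacher forcing) with per-pixel BCE.
* **Inference** — sigmoid scores, `score_thresh` filter, top-200 pre-NMS,
  greedy NMS (ties by lower input index), then a mask per kept box pasted
  into full-image coordinates at `mask_thresh` 0.5.

The anchor scales, pyramid depth, head widths and dilation placement are
config-surfaced defaults; no published values exist for them.  The
small-scale detection benchmark (2 levels, scales 24/40 px, 800
single-image SGD steps at lr 0.05 with a tightened negative threshold of
0.4 and NMS IoU 0.2) localises ≥ 80 % of held-out single-cell images with
exactly one detection at box IoU ≥ 0.5 on the majority of fixed seeds.

## Watershed

The flooding surface is the in-foreground geodesic distance from the
markers: a level-synchronous 4-connected BFS propagates marker labels
outward, and a pixel reached at equal distance from several markers takes
the **lowest** marker label.  Propagating the minimum neighbouring label per
BFS level provably assigns each pixel the smallest label among its
geodesically nearest markers, which is the documented tie rule; the test
suite checks pixel-exact agreement with an independent per-marker BFS
reference on random foregrounds.  Markers outside the foreground are
clipped with a warning; no markers yields an all-zero labeling.  After
flooding, 4-connected regions smaller than `min_region_pixels` (default 20)
are cleared — note this post-filter can also remove a tiny marker region,
so oracle tests run with it disabled.

In the pipeline the cytoplasm foreground is the union of the thresholded
detector probability map and the nucleus markers themselves (a nucleus
always belongs to its cell); markers are the connected components of the
thresholded U-Net nucleus map, eroded by one pixel for interiority (the
un-eroded component is used when erosion would empty it).

## Fusion

`fuse_probmaps` is a per-pixel convex combination (weights normalised to
sum 1), so the output is bounded by the per-pixel min and max of its
inputs.  `match_instances` matches instances one-to-one greedily by
descending mask IoU with ties broken by (lower id A, lower id B); greedy
rather than optimal assignment keeps the procedure deterministic and
transparent, and the tests verify it agrees with exhaustive assignment on
small fixtures.  `vote_instances` chains instances across all source pairs
through union-find on match edges; a group seen in at least `vote_min`
sources (default: strict majority) survives, its consensus mask being the
pixels covered by ≥ `vote_min` member masks, and consensus instances are
renumbered by descending area.  `resolve_overlaps` partitions contested
pixels by score, then centroid distance, then lower id; the fused
probability map is accepted in its signature for interface symmetry but the
documented rule never consults it.  The overlap-resolution rule is an
explicit stand-in for an optimisation step whose original description is
not available; it is deterministic, oracle-tested, and stated here in full.

In the pipeline the fused nucleus map combines the U-Net probabilities with
the hard probabilities of the extracted nucleus instance map (equal weights
by default; the one-pixel marker erosion is applied only when seeding the
watershed),
and the cytoplasm consensus votes between the watershed labeling and the
detector's instances before overlap resolution.

## Rotated-ellipse morphometry

`a` and `b` are **semi**-axes throughout (the enclosed area is `πab`);
orientation is degrees counterclockwise from the +col axis with period 180.
The fit is moments-based: centre = pixel centroid; axes from the
eigenvalues of the second central moment matrix scaled by `a = 2√λ₁`,
`b = 2√λ₂` (a uniform ellipse has second moments `a²/4`, `b²/4`).  Because
pixel quantisation perturbs the moment anisotropy of small or near-circular
regions, the orientation is then polished by a template-agreement scan:
candidate ellipses at ±10° around the moment angle (0.25° grid) are
re-rasterised and scored by inside-minus-outside pixel agreement, and the
centre of the argmax plateau is returned.  The generating ellipse
rasterises to the observed mask exactly, so this refinement is unbiased;
it is skipped for fitted aspect ratios below 1.02, where orientation is
not meaningful.  Masks with fewer than 5 pixels or collinear support are
rejected.  On rendered ellipses with `a ∈ [8, 30]`, `b ∈ [4, a]` the fit
recovers axes within 7 % and orientation within 5° (aspect ≥ 1.1).

## Evaluation

Object level: greedy one-to-one matching by descending mask IoU at
`match_iou` (default 0.5); `tp` = matches, `fp` = unmatched predictions,
`fn` = unmatched ground truths; precision, recall and F1 follow.  Empty
denominators use fixed conventions: precision 0 with no predictions but
non-empty ground truth (and symmetrically for recall); all metrics 1 when
both sides are empty.  Pixel level: Dice, Jaccard and accuracy; the
identity `D = 2J/(1+J)` is property-tested.  Pixel accuracy is reported
alongside object precision because "accuracy" in detection contexts usually
denotes the latter; emitting both avoids guessing intent.

## Determinism and numerics

Every stochastic component (generator, shuffling, dropout, anchor
subsampling, initialisation) draws from `numpy.random.Generator` instances
derived from the run seed; re-running any stage with the same configuration
is bit-identical.  Probability maps are validated to sum to 1 per pixel
within 1e-5; cross-entropy clamps probabilities at 1e-12; box decoding
clips log-size deltas to ±4 to avoid overflow from untrained heads; SGD
supports a global gradient-norm clip (1.0 for the U-Net, 5.0 for the
detector).  All arrays are float64 — at these model sizes the engine is
memory-bandwidth-light and the precision simplifies gradient verification,
which the test suite performs numerically against the analytic backward
pass.

## Known limitations

* The conv-net engine is minimal by design: stride-1 convolutions plus
  pooling, no batch normalisation, no momentum or adaptive optimisers.
* The detector trains one image per step and its mask head is
  teacher-forced on ground-truth boxes; at full Mask R-CNN scale one would
  sample proposals.
* Cytoplasm boundaries in heavy overlap are resolved geometrically (geodesic
  flooding, voting), not by a learned model of occlusion.
* The synthetic benchmark's difficulty is controlled by its noise and
  overlap settings; results on real HE-stained material will differ.
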