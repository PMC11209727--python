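# Methods

This note records the models, conventions, and numerical choices behind
`podkit`, and what the synthetic experiments do and do not establish.

## Representation and conventions

A pod is an unbranched chain of 1-5 seeds ordered from the pod base; a
seed dot labelled `"n-k(id)"` declares the pod's total seed count `n`, the
seed's 1-based ordinal `k` from the base, and the pod id. Coordinates are
0-based continuous pixels, x rightward, y downward; boxes are closed on
the min edge and open on the max edge. Pods whose ordinals are not the
full run `1..n` (produced legitimately by cropping and occlusion) are kept
and flagged *truncated*; their declared `n` is retained and the missing
slots are treated as sealed. The label grammar tolerates surrounding
whitespace and nothing else; `n > 5` is rejected, since the representation
fixes five keypoint types and larger pods are vanishingly rare in the
reference data (8 of 32,780 training pods).

## Crop geometry

Training crops are 400 x 400 px sampled around a chosen pod: the pod's
minimal bounding rectangle is expanded to the crop size with the
horizontal/vertical slack split uniformly at random, then shifted — never
shrunk or padded — to stay inside the image, so every crop has the exact
model input size. Inference tiles the image with a fixed stride
(default 300 px, i.e. 100 px overlap on a 400 px window; the overlap
comfortably exceeds one seed spacing so a boundary pod is whole in some
window or recoverable by merging). Train/test splitting happens at plant
level *before* cropping, so no pod can appear on both sides.

## Structural prior

Sample the C-channel feature vector `v_i` at each annotated seed position
(nearest cell after stride division; bilinear sampling is opt-in), form
the cosine-affinity matrix `A_ij = v_i.v_j / (|v_i||v_j| + 1e-8)` (the
epsilon makes zero vectors well-defined with cosine 0), and compare to the
binary same-pod matrix `A'` with the squared Frobenius distance. The loss
is summed per image without N^2 normalization in `sprior_loss`; the
trainer defaults to the per-entry-normalized variant
(`sprior_loss_normalized`) because crop-level seed counts vary by an order
of magnitude and a raw sum would make the effective prior weight depend on
scene density. The prior is a training-time term only.

Default loss weights: offset trade-off gamma = 0.03 and prior weight
rho = 0.2 in the reference loss API (`dekr_loss`, `total_loss`,
`LossWeights`).

## Prediction tensors, rendering, decoding

The detector predicts 6 heatmap channels (types 1-5 + background) and a
10-channel offset field at output stride 2 (toy setting). Rendering:
Gaussian peaks (sd 2 output cells, max-combined) per seed on its type
channel; background = 1 - max over type channels; heatmap weights
emphasize salient cells (peaks on type channels, seed areas on the
background channel — the informative region of the background channel is
where it *drops*). Offset targets are written around each pod's centre
(centroid of its present seeds) and point to every unsealed seed. Two
rendering details matter in crowded scenes: the supervision radius
(default 4 cells) is widened per pod until it reaches the seed nearest the
centroid, since spacing jitter can otherwise leave every actual heatmap
peak unsupervised; and cells claimed by several pods are assigned to the
pod with the nearest centre, so touching pods keep disjoint supervision
instead of overwriting each other.

Decoding mirrors rendering: candidate centres are local maxima of the
foreground above the heatmap threshold (default 0.3); each candidate
regresses five seeds through its offset vector; a regressed seed survives
if its type channel at the regressed position reaches the threshold, and
the pod keeps the surviving prefix chain from seed 1 (ordinals are defined
from the base, and the grammar cannot express interior gaps). Surviving
seeds are snapped to the nearby type-channel peak with sub-cell quadratic
refinement. Two physical gates stabilize crowded scenes: a chain stops if
a regressed (or refined) seed lands within `min_chain_step` (default 3 px)
of the previous seed — two seeds of one pod cannot coincide, and sealed
slots whose offsets are exactly zero regress onto the candidate itself —
and pose-level NMS visits candidates by descending (chain length, score),
suppressing a pod whose mean prefix-aligned seed distance to a kept pod
falls below `nms_thresh * nms_radius_per_unit` (10 px at the 0.05
default). Visiting longer chains first resolves nested partial duplicates
(a 1-seed fragment detected at the base of a full pod) in favour of the
complete detection.

## Toy trainer

The training harness exists to exercise the loss/metric/merging machinery
end to end at desk scale, not to reproduce a full-scale backbone. It is a
small plain convolutional network written directly on numpy (im2col-style
convolutions with hand-written backward passes, Adam): a stride-2 trunk
(5x5 then three 3x3 convolutions with dilations 1/2/4; receptive field
~49 px), a 1x1 heatmap head with sigmoid, a two-layer 3x3 offset branch,
and a two-layer structural-prior branch. The prior loss is applied to the
prior branch's output and reaches the trunk only through that branch;
applying it to the shared trunk features directly makes its gradient at
seed cells several times larger than the heatmap gradient and measurably
degrades detection.

Trainer loss terms: weighted per-entry-mean squared error on heatmaps;
smooth-L1 on offset residuals in cell units with the pod-scale normalizer
(1/Z, Z = sqrt of the pod's cell-bbox area) weighting the loss rather
than the residual (weighting the residual scales gradients by 1/Z^2 and
effectively freezes large pods); the normalized prior. The trainer's
offset trade-off defaults to gamma = 0.3 rather than the 0.03 of the
reference loss API: the reference value is calibrated against a *summed*
heatmap error, while the trainer's heatmap term is a per-entry mean, so
the balance point differs by the entry count's order of magnitude; 0.3
keeps both branches converging in the same schedule. Defaults: 60 epochs,
constant lr 5e-3 (an optional late 5x drop is off by default), batch 8,
horizontal-flip augmentation only (flipping preserves seed ordinals — the
chain is ordinal, not lateral). Training is deterministic given the seed
up to floating-point reduction order.

The prior branch taps the trunk mid-way (after the second convolution) by
default rather than at the trunk output. The tap point is exposed as a
configuration choice; the mid tap is the default because the prior's
objective — making same-pod seed features identical — directly opposes
the offset branch's need for spatially distinct features at those same
cells, and applying it to the shared final features measurably degrades
offset regression in this small network while the mid tap leaves the late
dilated convolutions free and improves detection alongside the prior.

## Evaluation

`OKS_pod` divides each squared seed distance by `2 lambda_n s^2 k^2`:
`s` is the object scale (square root of the seed bounding rectangle's
area after expanding by one seed radius per side — the annotations are
keypoint-only, so the box needs a physical pad; configurable),
`k = 2 sigma`, and `lambda_n` is the per-type area correction (reference
values 4.752, 1.353, 1, 0.782, 0.673; `estimate_lambda` recomputes them
as mean per-image bbox-area ratios of 3-seeded to n-seeded pods, and
`lambda_3 = 1` identically). `sigma` defaults to 0.05; `estimate_sigma`
calibrates it from a relabelled subset via `sigma^2 = E[d^2/s^2]` — note
`d` is the 2-D Euclidean distance, so per-axis jitter of relative sd `c`
yields `sigma = c sqrt(2)`. Unmatched seeds contribute `exp(-inf) = 0`
while the 1/n normalization keeps the declared seed count, so partial
detections are penalized but not renormalized away. With `lambda_n`
equalized, pods of different seed counts facing equal per-seed distances
score identically — the stated purpose of the correction.

AP follows the COCO convention the metric family comes from: greedy
matching in descending detection score (ties on ground-truth index),
all-point PR interpolation, AP = mean over OKS thresholds 0.50:0.05:0.95
with AP50 also reported separately (both are emitted since reporting
conventions vary); per-type AP restricts ground truths to one seed count,
keeps detections matched to them, and counts an unmatched detection as
that type's false positive when its own chain length equals the type.
Counting quality is MAE and the sample Pearson correlation over images;
zero-variance series make the correlation undefined (NaN, logged).
Reported table statistics round half-up to 2 decimals.

## Merging

Per-tile detections are remapped to the full frame and merged to a fixed
point: (1) transitive duplicate collapse (same `n`, all ordinal-wise
distances below the duplicate radius) keeping the best-scoring copy;
(2) candidate pairs restricted to pods from different windows with seeds
inside the margin band around a shared window edge (band = intersection
of the two windows each expanded by `border_margin`, default the overlap
width); (3) pairs with a cross-pod seed pair closer than `dist_thresh`
(default 10 px), processed in ascending distance: a 1-seeded fragment —
or a fragment wholly duplicated inside the other — merges directly;
otherwise the chains are compared by DTW (Euclidean local cost, steps
(1,0)/(0,1)/(1,1), distance = optimal path cost / path length so the
threshold is length-comparable) and merge iff below `shape_thresh`
(default 15 px). Merged chains collapse path-aligned seed pairs closer
than the duplicate radius (score-weighted average), keep everything else,
re-order by projection onto the principal axis, orient the base from the
fragment whose own base seed had the higher confidence, and cap at five
seeds (excess lowest-confidence seeds dropped with a warning).

The duplicate radius is a separate knob (default `dist_thresh / 2`):
duplicated detections of one seed from overlapping windows are
near-coincident, while genuinely adjacent seeds sit one seed spacing
apart, and a single radius serving both roles collapses real seeds
whenever spacing drops below `dist_thresh`. Pair order and fixed-point
iteration make the result deterministic and idempotent.

## Synthetic data

The generator emulates exactly what the method consumes: seed coordinates
in near-collinear jittered chains, pod-type frequencies proportional to
the reference training counts (6,462 : 9,778 : 13,266 : 3,266 : 8 — the
1-in-4,000 rarity of 5-seeded pods included), touching pods via anchored
placement (`overlap_fraction`), Gaussian-blob rendering with background
noise, detector-noise fixtures (coordinate jitter, seed/pod dropout,
low-scoring spurious pods), and feature maps with prescribed
within/between-pod cosine similarity built from mutually orthonormalized
pod-identity, shared, and per-seed directions (exact in expectation while
the direction count fits the channel count). Two physically motivated
constraints matter: seeds of different pods keep a minimum separation
(default two seed radii — rigid seeds can touch but not interpenetrate;
this also keeps same-type heatmap peaks of touching pods resolvable at
the default rendering sd), and a faint
pedicel ridge extends from the base seed away from the chain. The pedicel
is not cosmetic: without it the two ends of a rendered pod are visually
interchangeable, the base-to-tip ordering is unobservable from pixels,
and the ordinal heatmap/offset tasks are ill-posed; real pods hang from a
visible pedicel.

What the generator does **not** model: photometric realism (colour,
lighting, camera optics), leaves/stems/background clutter, perspective,
in-plane pod curvature beyond small jitter, and annotation error beyond
isotropic jitter. Passing tests therefore demonstrate the correctness of
the geometry, losses, metrics, decoding, and merging machinery — not
field performance on real plants.

## Desk-scale study sizes

The smoke ablation trains on 200 synthetic 128 x 128 crops (1-3 pods
each, seed spacing 12 px, radius 4 px) for the two prior weights
rho = 0 and rho = 0.2 with identical seeds, and evaluates AP50 (sigma
0.05, bbox pad = seed radius) and the held-out normalized prior loss on
30 unseen scenes. Round-trip suites use 50 seeded scenes each. These
sizes were chosen so the full pipeline — including both training runs —
executes in minutes on a single CPU while every stage still runs at a
nontrivial scale.

## Known limitations

- The decoder implements the pixelwise-regression reading of keypoint
  grouping; associative-embedding-style grouping is a different mechanism
  and is not provided.
- The toy network is not a high-resolution backbone; its absolute AP
  numbers characterize the synthetic benchmark only.
- `estimate_lambda` needs images containing both 3-seeded and target-type
  pods; entries without qualifying images keep the reference defaults and
  are flagged.
- Merging is greedy and local (per pair, ascending distance); it does not
  globally optimize over all fragment assignments.
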