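# Methods

This note documents the models and procedures implemented in
`pestvision`, the parameter choices that matter, what the synthetic
fixtures do and do not emulate, and the numerical/design decisions made
where the problem left them open.

## Saliency model

An input image is partitioned by efficient graph-based (minimum
spanning tree) segmentation: pixels are nodes of an 8-connected grid
graph weighted by Euclidean RGB difference, and two components merge
when the connecting edge weight does not exceed the minimum internal
difference plus `k/|C|`. The merge itself is delegated to
`skimage.segmentation.felzenszwalb`; the wrapper enforces consecutive
labels and the minimum region size. Defaults `k = 300` (0–255
intensity scale, mapped to skimage's float scale as `k/255`),
`smooth_sigma = 0.8`, `min_size = 100` were chosen to produce coarse
partitions (roughly 5–50 regions) on ~160–256-pixel images; the
saliency model is deliberately insensitive to the exact partition
because contrast is aggregated over all regions.

Colors are quantized per RGB channel into `bins` equal intervals
(default 10, so 10³ producible colors); the palette entry of a bin is
its center. Each region's color histogram weights a palette-level color
distance:

```
D_r(r1, r2) = Σ_i Σ_j p(c_1i) · p(c_2j) · D(c_1i, c_2j)
S(r_k)      = Σ_{i≠k} exp(−D_s(r_k, r_i) / σ_s²) · ω(r_i) · D_r(r_k, r_i)
```

with `ω(r_i)` the region pixel count and `D_s` the Euclidean distance
between centroids normalized per axis to [0, 1]. The raw values are
min-max normalized and broadcast to pixels; degenerate cases (a single
region, or all contrasts equal) render as an all-zero map rather than
an error so batch pipelines proceed.

Decisions taken where the formulation was open:

- **Spatial weight.** `exp(−D_s/σ_s²)` with `σ_s = 0.45`: a large σ_s
  weakens the spatial decay, so contrast against *far* regions still
  contributes — the behavior the global-contrast method is named for.
- **Color distance space.** Default `D` is Euclidean distance in
  CIELab between palette colors, scaled so the maximum over all palette
  pairs is exactly 1 (the maximizing pair is found by brute force; in
  Lab it is a blue↔yellow pair, not black↔white — black↔white attains
  the maximum only under the alternative `rgb` metric, which is kept
  available behind `color_metric`).
- **Size weighting** uses the *other* region's pixel count (`ω(r_i)`
  inside the sum over `i`): large regions dominate everyone's contrast,
  which is exactly why a small object on a large background saturates
  at saliency 1 after normalization.
- No histogram sparsification or color-space smoothing is applied; the
  quantization is coarse enough at 10 bins that both refinements change
  desk-scale maps negligibly.

The optimized vectorized evaluation is tested for exact (≤1e−9)
agreement with an independent nested-loop implementation on random
multi-region instances.

## Localization

The saliency map is thresholded at `th = 0.3` (a sweep utility covers
0.1–0.9); the binary map initializes GrabCut with *probable*
foreground/background labels only — no hard constraints — so the cut
may relabel any pixel. GrabCut alternates (i) fitting 5-component
full-covariance Gaussian mixtures to the current foreground and
background colors (scikit-learn, ≤10 EM steps per round, fixed seed)
and (ii) solving an s-t min-cut (igraph) with data terms equal to the
negative log-likelihoods and contrast-sensitive pairwise terms
`γ/dist · exp(−β‖z_i−z_j‖²)`, `γ = 50`,
`β = 1/(2⟨‖z_i−z_j‖²⟩)`, on the 8-neighborhood. Three rounds are run
by default. The soft initialization is what lets color evidence recover
thin appendages (legs/antennae) that region-level saliency misses.

The largest 8-connected component's tight box (ties broken toward the
top-left) is extended to a square of side `max(w, h)`: the short axis
grows symmetrically, squares crossing an image edge are shifted inward,
and if the side exceeds the image's short dimension the square is
clamped to it. Padding is never fabricated. The square is cropped and
bilinearly resized to 256 × 256. Degenerate stages fall back: an empty
or full threshold mask skips GrabCut; a fully empty mask yields the
whole-image square with `fallback_used` set, so database construction
can flag (rather than drop) failures.

Correctness of a predicted box against a ground-truth box requires
(1) `|A_pred − A_gt| < 0.2·A_gt` and (2) `|pred ∩ gt| / A_pred ≥ 0.8`.
Both restrictions are asymmetric by construction and are evaluated on
boxes, not masks, since ground truth is box-level. All coordinates are
0-based, half-open, everywhere including annotation CSVs.

## Classifier

The reference network (Type-1): Conv1 128 filters 11×11 stride 3,
Conv2 256 @5×5 pad 2, Conv3–4 384 @3×3 pad 1, Conv5 256 @3×3 pad 1;
ReLU after every conv/FC hidden layer; overlapping 3×3 stride-2 max
pooling after Conv1, Conv2 and Conv5; FC6–7 of 4096 units with
inverted dropout (ratio 0.7); a final 12-way layer under softmax
(one-versus-all linear hinge available). Weights are initialized
N(0, 0.01²), biases 0. Local response normalization and grouped
convolutions are omitted. Training is plain SGD: momentum 0.8, L2
weight decay 0.005, learning rate 0.01 divided by 10 at each epoch
boundary, mini-batches of 128, with 5 random 227×227 crops and
horizontal mirrors as training views and a single center crop at
evaluation.

Presets 2–7 remove FC7; FC6–7; then additionally Conv5, Conv4, Conv3,
Conv2. Presets 8–10 shrink Conv2–5 widths to (192,320,320,192),
(128,256,256,128), (64,192,192,64). **Geometry of ablated nets:** the
terminal pooling stage is always retained — when conv layers are
removed, the deepest remaining conv layer is followed by the final
3×3/2 pool in addition to its own. This keeps the classification
layer's input compact and makes parameter counts strictly decreasing
along the removal sequence; without it a Conv1-only network would feed
a 36×36×128 map straight into the classifier and carry *more*
parameters than deeper ablations. `count_parameters` walks the exact
layer geometry; the Type-1 count under these conventions is
87,907,084 (stride-3 Conv1 yields an 8×8×256 map into FC6, larger than
classic stride-4 variants, so the count exceeds the ~60M of those).

### Desk-scale profile

Full-scale training (3 × 20000 iterations at 227 px) is far outside a
workstation test budget. The documented desk-scale profile —
`reduced()` (64-px inputs, conv widths ÷4, FC widths capped at 256)
plus `desk_config()` (batch 16, 2 × 250 iterations, crop 64) — keeps
the full topology, schedule and regularization. One profile parameter
differs from the full-scale recipe: initialization std 0.05 instead of
0.01. At a quarter of the width and depth of signal aggregation, the
0.01 init leaves forward activations so small that gradients vanish and
SGD never leaves the plateau; 0.05 restores a usable signal scale.
Evaluation reports argmax accuracy, per-class precision/recall,
one-vs-rest ranked average precision per class (scikit-learn) and
their mean as mAP; mean per-class precision is reported alongside
because on an evenly distributed test set the two coincide closely.
Classes absent from an evaluation split have undefined AP and are
excluded from mAP with an explicit warning.

## Synthetic fixtures

Localization scenes place one insect-like object — a tilted filled
ellipse (semi-axis 10–15% of the short image side, box aspect sampled
log-uniformly in [0.35, 2.8]) with 2–6 thick line appendages — on a
dark muted green-brown background textured with smoothed value noise,
plus 0–8 Gaussian-blurred distractor blobs. The object's mean color is
placed at the requested normalized-RGB distance (`contrast`) from the
background base color along the direction of the farthest RGB-cube
corner, so the contrast dial is metrically meaningful and monotone.
The generator records the exact object mask and tight box. Suites
derive per-scene seeds as `suite_seed + index`; the `easy` preset draws
contrast from [0.75, 1.0] with light clutter, the `hard` preset lowers
contrast to [0.45, 0.8] and adds strong, heavily blurred clutter —
emulating background bokeh, the known failure mode in which background
regions acquire high saliency. Default scene size is 160 × 160, chosen
so a 50-scene end-to-end evaluation runs in well under a minute.

Classification datasets assign class *i* the (shape family *i* mod 6,
hue band *i* mod 4) combination — distinct for every *i* < 12 —
rendered with random pose/scale jitter on gray textured backgrounds,
split 75/25 into train/val per class.

What the fixtures do **not** emulate: photorealistic insect texture,
occlusion, pose articulation, illumination changes, multiple objects,
and real inter-species similarity. Passing the localization recovery
check therefore demonstrates that the saliency + GrabCut machinery is
implemented correctly and behaves as designed on images matching its
operating assumptions (single high-contrast object, muted background);
it does not certify field-image accuracy. Likewise, perfect accuracy on
shape/hue classes shows optimization and evaluation correctness, not
fine-grained recognition ability.

## Numerical notes and limitations

- All randomness flows through `numpy.random.Generator` seeds; suites,
  GrabCut, training and the pipeline are bit-reproducible for a fixed
  seed. The pipeline derives stage seeds from one global seed by fixed
  offsets (+100 scenes, +200 dataset, +300 training).
- Min-max normalization maps constant saliency to all-zero (not all
  one): an image with no contrast should localize nothing.
- GrabCut subsamples color-model fitting at 20k pixels and runs ≤10 EM
  iterations per round; the cut, not EM convergence, drives refinement.
- `extend_to_square` can return a non-square box only when the image
  itself is smaller than the object box's long side in one dimension
  (the clamped case).
- The hinge-loss subgradient at a kink takes the inactive branch
  (gradient 0), the usual convention.
- Known limitation: the region-saliency stage is O(R²·C) in regions ×
  palette; fine segmentations (thousands of regions) would need the
  sparse-histogram optimizations that the coarse default segmentation
  makes unnecessary.
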