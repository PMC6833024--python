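# Methods

## Segmentation model

The network (MSMKU) is a U-shaped encoder–decoder whose contracting path
consumes an image pyramid rather than a single image.  An input of side
`W` (square, divisible by 16) is area-resized to sides `W/2`, `W/4`,
`W/8`; each level `X_i` passes through a small convolutional stem `f_i`
(one 3×3 convolution, ReLU, batch normalisation).  The full-resolution
stem additionally ends in a strided convolution so that its output
matches the second level, which makes the additive fusion chain

    F3(F2(F1(f1(X1) + f2(X2)) + f3(X3)) + f4(X4))

produce feature sizes `W/4`, `W/8`, `W/16`.  Each `F_i` is a
multi-kernel residual module followed by a 3×3 stride-2 convolution; no
pooling layers are used anywhere.  The multi-kernel module runs four
parallel branches — three 3×3 convolutions and one branch of two
successive 4×4 convolutions — concatenates them along channels, mixes
with a 1×1 convolution (ReLU, batch norm) and adds a short connection
from the module input (1×1-projected when widths differ).  The expanding
path mirrors the four halvings with (bilinear ×2 up-sampling, 3×3
convolution) stages, adds the pre-strided module outputs as skips, and a
final 1×1 convolution + sigmoid yields a probability map at input size.

Width and depth choices the architecture description leaves open were
fixed as follows: channel width starts at `base_width` at full
resolution and doubles at every halving; each stem is a single
convolution block; multi-kernel branches carry half the module's output
width (their concatenation is then twice the module width before the 1×1
mix); up-sampling precedes the decoder convolution; the decoder
convolution maps to the skip's width so skips add without projections.
Even 4×4 kernels preserve spatial size with asymmetric padding (1
top/left, 2 bottom/right).  Working resolutions are 384 for disc
segmentation and 256 for cup segmentation; tests and phantom experiments
use 64 with `base_width` 4 (~90k parameters) so a forward pass takes a
few milliseconds on one CPU.

The implementation is pure NumPy.  Stride-1 convolutions are evaluated
as one BLAS matrix product per kernel offset on row-flattened
zero-padded inputs (padding absorbs cross-row leakage, so no im2col copy
is needed); strided convolutions use numba-compiled im2col/col2im patch
kernels around a single product.  Batch normalisation keeps running
statistics; inference always uses them, so prediction is deterministic.
The entire backward pass is validated against central finite differences
in float64 (relative tolerance 1e-4).  One caveat discovered there:
with zero-initialised biases, zero-padded corners can put
pre-activations exactly on the ReLU kink, where the subgradient and the
symmetric difference quotient legitimately differ — gradient tests
therefore nudge biases off zero first.

## Loss and training strategies

The training loss is the soft Dice loss on the probability map,

    l(P, G) = 1 − 2 Σ P·G / (Σ P² + Σ G²),

with gradient taken directly in P (no thresholding inside training).
Both masks empty is rejected as undefined; at evaluation time the same
quantity on a binarised P equals 1 − F exactly.

Three strategies share one loop (Adam, lr 1e-4, β₁ 0.9, β₂ 0.999,
ε 1e-4, batch size 4):

- **ALM** minimises the per-sample loss sum over all m samples.
- **MLM** minimises the sum over the N_t currently-worst samples.
- **MMLM** minimises  λ₁ Σᵢ l(f(Xᵢ), Yᵢ) + λ₂ Σ_k Σ_j l(f(R_k(X̄_j)), R_k(Ȳ_j)),
  where X̄_j is the j-th worst sample under the parameters frozen at the
  end of the previous round and R_k is a random rotation/translation.

Defaults: λ₁ = 1, λ₂ = 2, N_max = 40, N_min = 5, K_max = 15, K_min = 4.
The schedules are N_t = max(N_max − t, N_min) (clamped to m) and
K_t = max(K_max − ⌊0.25 t⌋, K_min); the K_t floor is applied to the
product 0.25·t so the fold count actually decreases by one every four
rounds and reaches its floor, matching the schedule's described
behaviour.  One "round" is one epoch of mini-batch Adam over the
weighted multiset (all m originals at weight λ₁ plus K_t augmented
copies of each top-N_t sample at weight λ₂, shuffled with a round-seeded
generator); ranking happens once per round with frozen weights, so
within-round parameter drift does not affect sample selection.  Batch
losses are weighted sums (not means), so λ₁ = 0 / λ₂ = 0 reduce exactly
to MLM / ALM.

Augmentation draws rotation uniformly in ±20° and translation uniformly
in ±5% of the image side (label-preserving, mild; ranges are free
parameters of the method).  Images interpolate bilinearly, masks by
nearest neighbour, out-of-frame pixels fill by reflection.  Every op is
derived from the tuple (seed, t, k, j), so runs are bit-reproducible.

## Two-stage pipeline

Stage 1 resizes the image to the disc network's side, predicts, applies
the fixed 0.5 threshold, and restores the disc mask to source
resolution.  A square ROI is the disc's tight bounding box expanded by
half its larger side in every direction (margin 0.5, configurable;
chosen to contain the cup generously even under disc under-segmentation),
clipped square by shifting inward; an empty disc mask falls back to a
centred box of half the image side.  Stage 2 crops and resizes the ROI
to the cup network's side, predicts, thresholds, and pastes the cup mask
back at the recorded coordinates.  Crop→restore at matched sides is an
exact involution, and the cup mask is zero outside the ROI by
construction.  No cup⊆disc constraint is imposed by default (an optional
flag intersects them).  Non-square images are resized anisotropically.
During training the cup network sees ROIs derived from ground-truth disc
masks; at inference ROIs come from predicted masks — with disc F-scores
near 0.98 on phantoms the induced shift is small.

## Screening

VCDR is the ratio of vertical pixel extents (bounding-box extent, not
longest column run) of cup and disc masks.  Rim widths cast 360 rays at
1° steps from the disc centroid; per ray the rim width is the radial
distance from the outermost cup crossing (the centroid when the cup is
absent on that ray) to the outermost disc crossing, sampled at 0.5 px
steps.  Sector means over 90° quadrants centred on image-down (I),
image-up (S) and the two horizontal directions give (I, S, N, T), with
nasal/temporal assigned by a laterality flag (default right eye: nasal =
image-left; "unknown" falls back to max/min).  The ISNT score counts
strict inequalities among I > S, S > N, N > T.  This radial-quadrant
construction is this package's concrete realisation of the qualitative
clinical rule, not a standardised formula.  The default screening
statistic is VCDR alone (an optional γ term adds the ISNT violation
count); AUC is the exact Mann–Whitney rank statistic with ties counted
one half.

Degenerate-input conventions in the metric layer: empty prediction of an
empty target counts as vacuously perfect (precision = F = IoU = 1);
specificity is 1 when there are no negatives; all conventions are
monotone and never produce NaN.

## Synthetic phantoms

A phantom is a square RGB image: radial-shaded reddish background,
bright elliptical disc, brighter elliptical cup strictly inside it, 3–6
dark Bézier vessel strokes crossing the disc (cosmetic only, never in
the masks), Gaussian pixel noise (σ = 6 of 255).  Masks are exact
ellipse interiors, so VCDR is known analytically as the cup's vertical
fraction; rendered-mask VCDR matches it to well within 0.05 at side 64.
Populations draw disc semi-axes 0.28–0.36 of the side, cup vertical
fractions 0.3–0.8 (typical), cup-rim contrast 0.45–0.9, and an
off-centre cup.  Rare styles mirror the clinically hard minority:
`small_cup` (vertical fraction 0.08–0.2) and `low_contrast` (contrast
0.05–0.15); `generate_dataset` makes ⌈rare_fraction·n⌉ of them at
deterministic positions.  Glaucoma labels are VCDR > 0.6 — a rule chosen
so that perfect masks separate the classes exactly (screening AUC 1),
which pins down the screening stack's correctness.

What phantoms do not emulate: camera vignetting and colour balance,
peripapillary atrophy, vessel-induced cup boundary ambiguity, inter-rater
uncertainty, or anatomical texture.  Passing tests demonstrate that the
mechanisms (losses, ranking, schedules, pipeline geometry, screening
arithmetic) are implemented correctly and that hard-example re-weighting
behaves as described on an imbalanced population — not that clinical
accuracy figures transfer.

## Experiment scale and reproducibility

The bundled strategy comparison uses 60 phantoms at side 64
(rare_fraction 0.15), a stratified 41/19 split that keeps rare styles in
both halves, `base_width` 4 networks and 30 rounds per strategy; ten
seed replicates compare the minimum held-out rare-style F-score of MMLM
and ALM.  These sizes were chosen so the whole experiment runs in
minutes on a single CPU while leaving the compared conditions identical
between strategies.  All randomness flows from named integer seeds
through `numpy` `SeedSequence`s; histories, weights and CSV outputs are
bit-identical across runs with equal seeds.

## Known limitations

- The NumPy engine trains tiny networks comfortably but is not suited to
  full-resolution (384²) training at realistic widths.
- Batch normalisation statistics at batch size 4 are noisy; inference
  uses running averages, so train/eval outputs differ slightly.
- The ISNT rim construction is centroid-based and assumes a roughly
  convex disc; severely fragmented predicted masks can distort VCDR
  (no connected-component post-processing is applied).
- The cup network trains on ground-truth-disc ROIs; a poorly performing
  disc network at inference time shifts the cup input distribution.
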