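# Methods

## Problem and model

`nodulecomp` segments lung nodules in 2-D CT patches. Nodules vary widely
in size, shape and intensity, and the hardest cases (juxta-pleural,
juxta-vascular, ground-glass, cavitary) share intensity with the tissue they
touch, so a plain encoder–decoder blurs exactly the boundary a radiologist
cares about. The network mirrors the clinical reading order — locate the
nodule, outline its coarse extent, refine its edge — by decoding high-level
(semantic) and low-level (edge-rich) backbone features separately and then
letting them complement each other.

The feature extractor is a Res2Net50-style five-stage pyramid in which the
classification stem's 7×7 convolution is replaced by three consecutive 3×3
convolution(+BN)+ReLU stages and the global pooling / fully connected head
is removed. Taps f1 (stride 2) and f2 (stride 4) are the low-level
features; f3, f4, f5 (strides 8/16/32) the high-level ones. The stage
strides (2, 4, 8, 16, 32) follow the standard Res2Net50 layout; the first
stem convolution carries the ×2 downsampling.

**MF block** (multi-receptive-field). Four cascade branches b0..b3: a 1×1
channel reduction to 32, then for m ≥ 1 a factorized 1×(2m+1)/(2m+1)×1 pair
followed by a 3×3 convolution with dilation rate 2m+1. For a stride-1 chain
the receptive field grows by (k−1)·d per layer, giving branch fields of
1, 9, 15 and 21 input pixels. Branch outputs are concatenated (4×32→32 via
a 3×3 convolution) and a 1×1-projected shortcut is added element-wise.

**MD block** (cross-scale decoder). With f5″ = f5′ fixed at the deepest
level, each shallower refined feature is multiplied element-wise by every
deeper feature (bilinearly upsampled, 3×3 conv + BN, no activation — the
gate stays signed):

    f4″ = f4′ ⊗ Conv(Up(f5′→f4′))
    f3″ = f3′ ⊗ Conv(Up(f4′→f3′)) ⊗ Conv(Up(f5′→f3′))

f3″, Up(f4″) and Up(f5′) are concatenated at f3's resolution and reduced by
two 3×3 and one 1×1 convolution to the 1-channel coarse logit map fg.

**LE block** (low-level edge). fE = f2 ⊕ (f1 ⊗ f2) after per-input 1×1 and
3×3 filters; the sum keeps complementary features, the product enhances
shared ones. fE lives at f2's resolution (stride 4, 32 channels): f1 is
average-pooled down rather than f2 upsampled, to keep memory moderate.

**Complementary module.** Location fusion gates f4′ with a sigmoid of the
processed, upsampled f5′, upsamples the gated location map to fE's
resolution and adds it point-by-point, producing the edge guidance fE^.
Edge fusion adds the processed, upsampled coarse map to fE^ in logit space
(pre-sigmoid), projects to one channel, bilinearly upsamples to the input
resolution and applies a sigmoid: the segmentation probability map Ps.
A 1×1 sigmoid head on fE^ gives the edge probability used for edge
supervision; since the supervision compares against a binary edge map, this
head is required even though it has no learned semantics of its own.

## Losses

Per-pixel importance weights W = α + β·|Gs − mean_pool(Gs)| with α=1, β=5
and a 31×31 same-size mean pooling (stride 1, reflective padding; 31 makes
the boundary halo several pixels wide at 96×96). The absolute value keeps
W ≥ α everywhere — off-edge pixels sit at the low constant α. The
segmentation loss is the mean of a W-weighted binary cross entropy
(normalized by ΣW; local) and a W-weighted IoU loss (global structure).
Edge supervision is a mean-reduced BCE between the edge probability and the
morphological-gradient (3×3 dilation − erosion) edge map of Gs, computed at
the edge head's resolution after nearest-neighbour downsampling of Gs and
re-thinning. The total loss is their unweighted (1:1) sum, plus — default
on — the same weighted segmentation loss on the sigmoid of the upsampled
coarse map fg as deep supervision. Probabilities are clipped to
[1e-7, 1−1e-7] before logs. An all-empty weighted-IoU denominator is
defined as zero loss with a warning.

## Training regime

Adam, initial learning rate 1e-4 multiplied by 0.9 every 30 epochs, batch
size 4, up to 60 epochs, early stopping 10 epochs after the best validation
DSC (the held-out split doubles as validation; there is no third split).
Patches are resized to 96×96; each training step draws one scale from
{0.75, 1, 1.25} and resamples the whole batch (bilinear images,
nearest-neighbour masks) — scale-jitter training with a single shared
network rather than three parallel passes (a config flag `multiscale`
disables it). Evaluation always runs at scale 1. Patient-level 9:1 split:
all crops of a patient land on one side. Binarization threshold 0.5.
A non-finite loss aborts training with the last good checkpoint retained.

## Numerical substrate

No GPU framework is used: the package carries a compact numpy
reverse-mode autodiff layer (`nodulecomp.nn`) with hand-written backward
passes for convolution (im2col), batch norm, max/average pooling and
bilinear resizing (half-pixel centres; constant maps resize to constants
exactly), verified against finite differences in the test suite. Weights
use He initialization from a seeded generator, so runs are bit-reproducible
on CPU. A width multiplier scales all channel counts, and the per-stage
block counts are configurable, so tests train desk-scale networks; the
default (width 1.0, blocks 3/4/6/3) matches the full architecture.
ImageNet-pretrained weights are not bundled; a checkpoint path may be
supplied and a missing file is a hard error, never a silent random init.
Batch-norm statistics are not frozen when loading external weights.

## Synthetic phantoms

The generator emulates the statistical structure of clinical nodule
patches, not CT physics: dark parenchyma (base intensity 0.15) with
additive Gaussian noise (σ = 0.05 default), nodules as randomized
star-convex polygons (16 vertices, jittered angles, radial perturbation
±25% — irregular, mildly spiculated margins whose area stays within
[0.5, 1.5]× the equivalent disc). Types: isolated (contrast 0.6),
juxta-pleural (touching a bright wall band, 0.8 intensity), juxta-vascular
(crossed by a bright tube), GGO (contrast 0.25 ≤ 0.3), cavitary (interior
lucency with a filled reference mask, per contouring convention), calcified
(contrast 0.95). Five crops per nodule with independently drawn per-side
margins give non-centred, non-square, aspect-varying patches, all resized
to 96×96 (nearest-neighbour for masks, so they stay binary). Synthetic
patients occupy disjoint seed ranges, making the patient-level split
meaningful. What passing tests show: the architecture, losses and pipeline
optimize and generalize on images with the right *relational* structure
(attachment, low contrast, cavitation). What they do not show: performance
on real CT texture, scanner noise, slice-thickness effects or reader
variability.

## Evaluation

Eight measures per image, aggregated as mean, SD and a normal-theory 95% CI
(mean ± 1.96·SD/√n): DSC and JA (with JA = DSC/(2−DSC) as an internal
consistency check), HD95 (95th percentile of the pooled directed
point-to-set Euclidean distances, both directions, isotropic unit spacing
by default), sensitivity, specificity, S-measure (structure measure:
0.5·object-aware + 0.5·region-aware similarity, probability-map input),
E-measure (enhanced alignment of mean-centred binarized maps, (ξ+1)²/4
enhancement, M−1 normalization) and MAE. Conventions: empty-vs-empty gives
DSC = JA = 1; SE is undefined (excluded) when GT is empty, SP when GT fills
the field; HD95 of an empty operand is NaN with a warning and excluded from
aggregates.

## Desk-scale test conditions

The suite trains reduced networks chosen once as the package's own
desk-scale conditions: the learning-sanity check overfits 16 synthetic
patches for 160 Adam iterations (width 0.25, lr 1e-3, batch 4, scale jitter
off — the simplest regime that isolates "can the architecture fit at all")
and requires train DSC ≥ 0.85 on 2 of 3 seeds; the pipeline smoke test runs
the full synth → split → train → predict → eval chain for 2 epochs at width
0.125 with one block per stage. The learning rate for these scaled-down
runs is higher than the full regime's 1e-4 because tiny randomly
initialized networks on 16 images converge impractically slowly otherwise.

## Known limitations

2-D only; no HU calibration (intensities live in [0,1]); no pre- or
post-processing; numpy training is orders of magnitude slower than a GPU
framework and is intended for correctness, small studies and teaching, not
for full-cohort training; the phantom generator's crop positioning and
aspect-ratio ranges are exposed as configuration because no canonical
values exist for them.
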