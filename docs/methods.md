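# Methods

## The problem and the data model

Harvested tobacco leaves move along a conveyor belt mixed with foreign
material (NTRMs): weeds, rubber rings, feathers.  A line-scan hyperspectral
camera over the belt produces reflectance cubes of 101 bands on a 400–900 nm
grid at 5 nm.  The package treats a cube as an H×W×B float32 array with
reflectance nominally in [0, 1] (values up to 1.5 are tolerated at load for
specular glint; anything beyond is rejected as uncalibrated).  Detection
annotations are normalized center-format boxes `(class, cx, cy, w, h)`,
classes fixed as weed = 0, rubber_ring = 1, feather = 2.

## Synthetic scenes

The generator paints a per-pixel material map: a dark, spectrally flat belt;
`n_leaves` overlapping elliptical tobacco leaves; then the requested NTRMs —
weeds as unions of elliptical lobes, rubber rings as annuli, feathers as
elongated thin ellipses — placed by rejection sampling with no NTRM–NTRM
overlap (an over-full scene raises after 100 attempts per object).  Boxes
are tight to the pre-occlusion masks; optional occlusion paints an extra
leaf over part of an object but never deletes its box, matching the
training goal of detecting partially hidden contaminants.

Material templates are hand-designed smooth curves constrained by the
qualitative structure of belt-scene reflectance rather than fitted values:
tobacco has a 550 nm green peak, a ~680 nm chlorophyll trough, a red-edge
rise over 680–750 nm and an NIR plateau ≥ 0.4; weed shares the red edge but
with a stronger green peak and a lower plateau; rubber is flat mid-gray
(SD < 0.03 across bands); feather is bright and featureless; belt < 0.1
everywhere.  Validated invariants: all curves smooth (adjacent-band step
< 0.05) and tobacco–NTRM contrast concentrated in 550–850 nm rather than
455–545 nm for at least two of the three classes.

Pixel-level variation is **spectrally smooth** multiplicative noise — a
per-pixel brightness mode plus a spectral-tilt mode, scaled so the per-band
SD equals the material's `jitter_sd` (0.02–0.04), plus a small white
component at one tenth of that.  Real reflectance noise is band-correlated;
a white noise model would also make high-order principal components pure
noise and the selected wavelength triple unstable between runs.  Global
illumination variation is a scalar gain drawn from [0.7, 1.3] (narrower in
the easy training regime below); belt motion blur is a uniform kernel along
the transport axis.  Scenes are bitwise reproducible for a fixed seed.

What the generator does **not** emulate: leaf venation and texture, cultivar
differences, stacking-induced shading, sensor stripe noise, and the full
3024×2464 frame (available via config, defaults are desk-scale).  Passing
tests therefore demonstrate the correctness and trainability of the
pipeline, not field performance on real belts.

Dataset assembly apportions boxes over scenes by the largest-remainder rule
(default rate 4.203 boxes per scene, class mix 4539 : 3243 : 4827), splits
scenes 6:2:2 (largest remainder), and derives per-scene seeds from one root
seed.

## Band selection

ROIs are pooled per material from the generated label maps (capped at
30,000 pixels per ROI; on full-size frames a practitioner would extract
8,000–30,000 pixels per ROI by hand).  Mean curves may be smoothed with a
cubic smoothing spline whose penalty is chosen by generalized
cross-validation — this reproduces constants and straight lines exactly.

PCA is computed on the **covariance** matrix of mean-centered, unscaled
reflectance restricted to the bands of a region (default 450–850 nm):
spectral bands share units, so correlation scaling would discard real
amplitude structure.  The weight-coefficient curve of component *i* is
γ_{i,j} = α_i · β_{i,j} (eigenvalue × loading at wavelength *j*).  Whether
the factor should be α or √α is immaterial for selection: extremum
locations are invariant to any positive per-component rescaling.

Selection takes the interior local extrema of γ (sign changes of the first
difference, plateaus propagated) plus the region endpoints, orders them by
|γ| descending (ties to the lower wavelength), and greedily keeps k = 3
candidates with pairwise separation ≥ 80 nm — the operationalization of
"widely separated peaks and troughs"; 80 nm admits a 580/680/850-style
triple with margin.  Fewer than k admissible candidates raises.

The component used for selection is a parameter.  On real belt cubes the
4th component of the 450–850 nm region isolates contaminant contours (a
visual judgment the package deliberately does not automate); on the
synthetic population that role falls to the 3rd component, whose selected
triple is bitwise stable across generator seeds, and desk-scale defaults
use it.

## Enhancement

PCC assigns the three selected bands to R/G/B by descending wavelength
(NIR-as-red false color) and min–max scales each band to 8-bit
independently (a constant band maps to zero).

DCS uses the symmetric whitening variant: with channel covariance
C = VΛVᵀ, pixels are centered, transformed by VΛ^{-1/2}Vᵀ (so channel
identity is preserved, unlike a PC-basis stretch), rescaled to a target SD
per channel, re-centered at the original channel means and clipped to
[0, 255].  The covariance is ridge-regularized by 1e-6·trace/3 unless
disabled; an all-constant image raises.  The target SD defaults to **100**:
about 2.5 SDs then span the 8-bit range, which is what display-stretched
DCS output looks like in practice, and it makes the inter-class mean color
distance on synthetic scenes strictly larger in DCS than in PCC — at SD 60
the dark channel means waste half the dynamic range below zero and the
property fails.  Saturation at the clip boundaries is accepted.

## Augmentation

Rotations are exact quarter-turns with closed-form box maps (90° CW:
(cx,cy,w,h) → (1−cy, cx, h, w), etc.); four of them compose to the
identity to 1e-12.  The occlusion overlay cuts a patch from a rectangle
free of any box (rejection sampling, ≤ 200 tries, otherwise the scene is
returned unmodified with a warning) and pastes it over a random
sub-rectangle covering 20–60 % of a random box's area; a box is dropped
only if its visible fraction falls below 0.3 — occluded-but-visible targets
keep their annotations to train occlusion robustness.  Each scene is joined
with `pick` = 2 of its three rotated variants, chosen per scene by the plan
seed; because rotation applies to every image modality stored on a scene,
RGB/PCC/DCS stay paired under identical choices.  Overlay, when enabled,
applies to each variant independently with probability 0.5.  Augmentation
runs after the split, within splits, so no variant of a held-out scene can
reach training (assertable via `source_id` provenance).

## Detector

One `ModelSpec` describes the whole family.  The **single-branch baseline**
is the standard small anchor-free layout: depth/width multiples 0.33/0.25
over base widths (64, 128, 256, 512, 1024), C2f backbone stages + SPPF, PAN
neck, decoupled head with DFL (reg_max = 16, box branch width
max(16, ch₃/4, 64), class branch width max(ch₃, n_classes)).  Instantiated
for 3 classes it has exactly 3,011,433 parameters and 8.08 GFLOPs at
640×640 — parameter totals are counted over all registered arrays
including the frozen DFL projection (the ecosystem accounting convention),
and FLOPs as 2×MACs of convolutions only.

The **dual-branch model** runs one backbone per modality (RGB and DCS),
concatenates P3/P4/P5 across branches and reduces each with a pointwise
convolution to the neck widths.  The BELFPN neck runs one top-down and one
bottom-up pass; every multi-input node computes Σ wᵢ/(ε+Σwⱼ)·Iᵢ with
learnable weights rectified to ≥ 0 (ε = 1e-4) and feeds a C2f_EL block.
C2f_EL keeps the C2f split/accumulate/fuse topology but its inner block is
an ELModule: a residual MBModule that splits channels three ways, applies a
depthwise convolution of a different kernel size per branch (BN + SiLU),
concatenates, channel-shuffles (groups = 2) and fuses pointwise.  Channel
alignment uses 1×1 convolutions after nearest upsampling (top-down) or 2×2
max-pooling (bottom-up).

The free architecture choices — neck widths, C2f_EL hidden channels,
kernel triples, downsample style — were fixed by a search over neck P5
width ∈ {160…256}, hidden channels in multiples of 6 (the shuffle/split
divisibility unit), kernel sizes from {3,5,7,9} with at least two distinct
sizes per triple, and downsampling ∈ {1×1+pool, 3×3 stride 2}.  The
adopted configuration — widths (64, 128, 160), hidden (48, 126, 132),
kernels (5,7,9)/(7,9,9)/(5,7,9), pooled 1×1 downsampling — totals exactly
3,733,674 parameters and 10.71 GFLOPs at 640×640.

Losses: BCE on class probabilities (clamped to [1e-7, 1−1e-7]), CIoU
(IoU − ρ²/c² − αv with v = (4/π²)(arctan(w_g/h_g) − arctan(w/h))² and
α = v/((1−IoU)+v) treated as a constant weight), and DFL supervising the
two bins flanking each continuous edge distance with linear interpolation
weights.  Weights λ_box/λ_cls/λ_dfl = 7.5/0.5/1.5.  Logarithms default to
natural base; a `base=2` toggle evaluates the printed-formula variant
(a constant gradient rescale).  Positives come from task-aligned
assignment: anchors inside a ground-truth box ranked by s^0.5 · IoU^6,
top 10 per target, conflicts resolved by IoU, soft class targets
normalized per target.

Training is plain Adam with linear warm-up (20 steps) and cosine decay —
deterministic for a fixed seed, single-threaded.  Inference decodes DFL
expectations into boxes at anchor centers and applies class-wise NMS
(IoU 0.7 default; 0.5 at desk scale where duplicate suppression on small
maps matters more).

The engine underneath (`dbytk.nn`) is a reverse-mode autodiff over numpy:
im2col convolutions (dense and depthwise) whose backward scatters with k²
vectorized adds, batch norm (momentum 0.03, eps 1e-3) composed from
primitives, max-pool with first-argmax subgradients, nearest upsampling.
All primitives are finite-difference checked; for quadratic test losses the
checks use a large symmetric step, which is exact and avoids float32
rounding in the oracle.

## Evaluation

Matching is greedy one-to-one in descending confidence with same-class
IoU ≥ threshold; AP integrates the monotone all-points interpolated PR
curve (an 11-point variant exists behind a flag); mAP@50-95 averages IoU
thresholds 0.50:0.05:0.95; classes absent from ground truth are excluded
from class means (0/0 is undefined, not zero).  The reported P/R pair sits
at the confidence threshold maximizing F1 over a 0.05-step sweep, since a
single operating point must be chosen.  The FPS harness reports the median
forward time after warm-up together with input size and batch; timing is
hardware-bound and never asserted.

## Problem sizes used by the test suite

Unit tests use toy matrices (≤ 10 bands) against brute-force oracles and
64–128 px scenes.  The end-to-end check trains the tiny dual-branch preset
(width multiple 0.25, neck 32/48/64, reg_max 8) for 200 iterations, batch 8,
lr 6e-3, on 20 easy synthetic scenes — 96×96, five NTRMs per scene balanced
over classes, object sizes 0.11–0.17 of the frame, no occlusion, gain in
[0.9, 1.1] — and evaluates 5 held-out scenes, reaching mAP@50 well above
0.5 in ~90 s on one CPU.  The augmentation-arithmetic fixture uses 1,000
annotation-fidelity (image-only, 48 px) scenes carrying exactly 4,203
boxes.

## Known limitations

* The numpy engine is CPU-bound and desk-scale; study-scale training
  (300 epochs, 640 px, batch 16 — recorded in `TrainConfig`) is far outside
  its envelope, so published full-scale detection accuracies are not
  reproduced here, only the architecture accounting and the pipeline's
  verifiable properties.
* DCS operates on the three selected bands only; no histogram
  equalization or pan-sharpening.
* The PC used for band selection remains a human choice between datasets;
  the package exposes it but does not score PC images automatically.
* The occlusion overlay composes with rotation by an explicit rule
  (overlay applied per rotated variant with probability 0.5); other
  compositions are conceivable and configurable.
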