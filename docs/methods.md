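# Methods

`nirvein` re-implements a complete near-infrared (NIR) vein imaging
software chain: synthetic phantom generation, grayscale enhancement,
Hessian-based centerline extraction, U-Net+ResNet18 segmentation with
BYOL encoder pretraining, and a variable-weight AD-Census stereo
matcher. This note records the models, the parameter choices that
matter, the numerical conventions, and what the synthetic experiments
do and do not demonstrate.

## Synthetic phantoms

Hemoglobin absorbs NIR strongly, so veins image as dark curvilinear
tubes on a brighter tissue background. The generator draws vessel
centerlines as cubic splines through jittered waypoints spanning the
field, rasterizes a constant-width tube around each (`distance to
centerline <= width/2`), and composes

    image = background * (1 - contrast * mask) + noise,

where the background carries a linear horizontal illumination ramp and
the noise is additive Gaussian. Defaults: 128x128, 3 vessels of width
3-7 px, contrast 0.5, background 0.75, ramp fraction 0.3, noise sigma
0.02. All intensities live in [0, 1] as float64 and are quantized to
8 bits only at file write, so the construction arithmetic is exact in
tests. Every output is a deterministic function of the seed.

Stereo pairs are built by forward-warping the left image with an
integer-valued disparity field; visibility conflicts are resolved
rightmost-wins (larger disparity = nearer surface), holes in the right
image are filled from the nearest written neighbor in-row, and the
validity mask excludes occluded pixels, out-of-frame correspondences
and a 1-px border. Restricting to integer disparities keeps the warp
exact: `left(r, c) == right(r, c - d)` holds bit-for-bit on valid
pixels, which the tests exploit. Real NIR pairs differ in ways the
phantom does not model — sub-pixel disparity, photometric asymmetry
between cameras, specularities, skin texture — so passing results here
demonstrate algorithmic correctness, not clinical performance.

A separate repetitive-texture pair generator builds the classic hard
case for local stereo: a vertical band of pure sinusoidal stripes
(period 8 px, smaller than the disparity) flanked by aperiodic
texture, with independent Gaussian sensor noise per eye and 8-bit
quantization. Independent noise matters: with bit-identical shifted
images, float-level asymmetries in the census transform resolve the
`d` vs `d - period` ambiguity artificially.

## Preprocessing

Contrast-limited adaptive histogram equalization followed by median
filtering. CLAHE clips each tile's 256-bin histogram at
`clip_limit * tile_pixels / 256` counts (relative clip factor,
default 2.0, grid 8x8), redistributes the excess uniformly, maps
through the scaled CDF, and interpolates the four neighboring tile
mappings bilinearly per pixel. A zero-variance tile uses the identity
mapping, so constant images pass through unchanged. Tile mappings are
CDF-based and therefore monotone. The median filter (default 5x5,
reflected borders) removes impulse noise while keeping vessel edges.
Note that CLAHE needs sensibly-populated tile histograms: on very
small images an 8x8 grid leaves ~150 pixels per tile against 256 bins
and the equalization degenerates toward identity; use a coarser grid
there.

## Centerline extraction

At vessel scale the Hessian of the smoothed image has one large
positive eigenvalue across the dark tube and one near zero along it.
Second derivatives are Gaussian derivatives (truncation 6 sigma, which
keeps discrete derivatives of smooth test functions near their
analytic values); eigenvalues come from the closed form for symmetric
2x2 matrices and are ordered |l1| <= |l2|. The line filter is the
standard two-eigenvalue vesselness

    V = exp(-(l1/l2)^2 / (2 beta^2)) * (1 - exp(-(l1^2+l2^2) / (2 c^2)))

gated to dark-tube polarity (l2 > 0), with beta = 0.5 and c = 15 on
sigma^2-normalized eigenvalues of 8-bit-scaled intensities; the
multi-scale response is the per-pixel maximum over sigma in {2, 3, 4}.
Thresholding (default 0.2) and morphological thinning give a 1-px
skeleton. Refinement removes components below `min_region_area`
(default 50 px), prunes spur branches shorter than `spur_length`
(default 10 px) by tracing from endpoints to branch points — a
junction-adjacent pixel is deleted with its spur when its remaining
neighbors stay mutually connected, which avoids leaving 1-px nubs —
and joins endpoint pairs of distinct components within
`max_gap_distance` (default 15 px) by straight rasterized segments,
nearest pairs first, with a union-find guard so joining never creates
redundant links. Component count never increases during refinement.

## Segmentation network

The U-Net keeps its decoder and skip connections; the encoder is the
ResNet18 layout: 7x7/2 stem, 3x3/2 max pool, then four stages of two
basic residual blocks with channels (64, 128, 256, 512) scaled by a
width multiplier. Inputs must be multiples of 32 (five halvings). The
decoder mirrors the five resolutions: each stage upsamples 2x
(nearest), concatenates the matching encoder feature map and applies
two 3x3 conv+BN+ReLU; a final upsample, conv block and 1x1 conv with
sigmoid produce per-pixel probabilities. The desk-scale profile
(width 0.25, i.e. 16/32/64/128 channels, 96x96 inputs) is what every
experiment here uses; it trains in minutes on one CPU. The full-width
profile exists but is untested at scale on CPU.

The whole stack — conv (tap-wise NHWC GEMMs, with an im2col path for
few-channel inputs), batch norm, pooling, Adam — is implemented in
float32 numpy with manual backpropagation; gradients were verified
against central finite differences in float64 to 8 significant
digits. Training is deterministic given the seed.

### BYOL pretraining

An online network (encoder + 2-layer projector + 2-layer predictor,
hidden 128, embedding 64, on the globally average-pooled bottleneck)
predicts the projection of a second augmented view computed by a
target network whose parameters are an exponential moving average of
the online ones. The loss per pair of views is

    L = 2 - 2 * cos(q(v1), sg(z'(v2)))

averaged over both view orderings (so L is bounded in [0, 4]); `sg`
is stop-gradient. Augmentations per view: random crop of 60-100% area
resized back, horizontal flip (p=0.5), brightness/contrast jitter
(+-0.2, p=0.8), Gaussian blur (sigma 0.5-1.5, p=0.2). Color-channel
augmentations from the BYOL reference are dropped (grayscale input).

Schedule: Adam with a 5-epoch linear warmup, cosine learning-rate
decay from 2e-3 to 0, a 10x learning-rate multiplier on the predictor
head, a fixed EMA momentum of 0.95, 50 epochs, batch 12. Two choices
matter at this small step budget (500 steps) and deviate from the
long-run BYOL reference values: the predictor multiplier keeps the
predictor tracking the projector so the bootstrap target stays
informative, and the fast EMA target (half-life ~14 steps, against
0.996+ in the reference) prevents the target from lagging so far
behind that training stalls in its early symmetry-breaking phase.
With both, the final-epoch loss lands in the 0.13-0.26 range across
seeds; with a uniform learning rate or a slow target, individual
initializations stall near 0.9. Batch 5 plateaus around 0.6-0.75 and
batch 24 leaves too few optimizer steps, which is how batch 12 was
chosen.

### Transfer and fine-tuning

Pretrained encoder parameters are copied by name into the
segmentation network's encoder; all layers remain trainable. The loss
is mean binary cross-entropy against the label mask, backpropagated
through the sigmoid in the numerically fused form (dL/dlogit =
(p - y)/N). A held-out split (25% by default) is scored each epoch
with BCE, IoU, Dice and boundary Hausdorff distance; the parameters
with the best Dice are checkpointed. Per-epoch training BCE is logged
both as the mean over mini-batches and as their sum, since both
reporting conventions appear in practice. Default Adam lr 1e-3,
batch 5; single-image overfitting demonstrations use a larger lr
because 200 small-batch steps at 1e-3 are not enough for this
CPU-scale network to collapse its training loss.

## Stereo matching

Costs combine absolute difference and census (9x7 window, 62-bit
string packed in a uint64, bit = neighbor darker than center,
symmetric-reflected borders) through the robust normalization
`rho(c, lambda) = 1 - exp(-c/lambda)` with lambda_AD = 10 and
lambda_C = 30 on the 8-bit intensity scale:

    C(p, q) = alpha * rho(C_AD, l_AD) + (1 - alpha) * rho(C_C, l_C).

With variable weights, alpha = 1 - exp(-1 / h_min), where h_min >= 1
is the minimum cross-arm extension of p in the left image: short arms
(edges) emphasize AD, long arms (homogeneous interiors) emphasize
census. Fixed mode uses alpha = 0.5. Out-of-frame candidates carry
the sentinel cost 1.0, the supremum of the normalized combination, so
winner-takes-all never selects them.

Cross arms extend per direction until the first rule failure. The
classic rule accepts extension k while |I(p) - I(p_k)| < tau and
k < L (strict, so the maximal extension is L-1; defaults L = 17,
tau = 20). The two-tier rule accepts k <= L2 while both the center
difference and the consecutive difference along the arm
|I(p_k) - I(p_{k-1})| are below tau1, and L2 < k <= L1 with both
below tau2 (defaults L1 = 34, L2 = 17, tau1 = 20, tau2 = 6). The
consecutive term compares the arm pixel with its inward neighbor,
which stops arms exactly at intensity edges; the same rule is applied
in both tiers and, by symmetry, to vertical arms with rows in place
of columns.

Aggregation follows cross-based cost aggregation: a horizontal-first
pass sums each pixel's own horizontal arm segment, then sums those
sums over the center pixel's vertical arm (the transpose for
vertical-first), tracking exact pixel counts so the aggregate is the
mean over the support region. Two iterations alternate pass order.
At disparity d the support uses the per-direction minimum of p's arms
and its correspondence q's arms in the right image. Disparity is the
per-pixel argmin (ties to the smaller disparity), refined by a
left-right consistency check (threshold 1 px), filling invalidated
pixels with the smaller of the nearest valid horizontal neighbors
(the background surface), and a 3x3 median; unfillable pixels keep
the inf sentinel, which is also what the PFM writer emits. The
scanline optimization stage of the classic AD-Census pipeline is
deliberately not implemented: only the cost and aggregation stages
are the subject here.

On the repetitive-texture pair the two-tier matcher's bad-pixel rate
is consistently at or below the classic one (about 3% vs 6.5% mean
over seeds at the default construction) because its arms, limited to
17 by the classic L, cannot reach the disambiguating aperiodic flanks
from the band interior, while the two-tier far tier (L1 = 34) can.

## Metrics

Binary cross-entropy uses natural log with predictions clipped at
1e-7. IoU = TP/(TP+FP+FN) and Dice = 2TP/(2TP+FP+FN); both are 1 when
both masks are empty, 0 when exactly one is. Hausdorff distance is
computed between mask boundaries (foreground pixels 4-adjacent to
background, image border counted as background) with an exact
Euclidean distance-transform fast path verified against the O(|A||B|)
definition; it is an error on empty sets. Disparity error reports the
mean absolute error and the percentage of pixels off by more than a
threshold (default 2 px), ignoring sentinel pixels. Illuminance
uniformity is min/mean over the receiving plane. Percent changes
between reported metric values are rounded to two decimals.

## Problem sizes

The experiments are sized for a single CPU: phantoms at 96x96 or
64x64, the width-0.25 network, stereo pairs up to 160 px wide with
disparity ranges up to 15. The pretraining acceptance run (120 images,
50 epochs) takes a few minutes; the full test suite runs in well under
half an hour.

## Known limitations

- The phantom's vessel profile is a hard-edged tube; real veins have
  soft absorption profiles, which would lower vesselness responses
  and soften census transitions.
- Stereo ground truth is integer-valued; sub-pixel estimation is out
  of scope, so the matcher's accuracy floor is 0.5 px on real scenes.
- The segmentation comparisons (transfer vs random init, Dice bars)
  are qualitative orderings on synthetic data; absolute metric values
  from the published comparison tables depend on the original dataset
  and training runs and are not reproducible here.
- CLAHE assumes 8-bit histograms; 16-bit inputs are rescaled.
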