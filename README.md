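# nirvein

A toolkit for near-infrared (NIR) vein imaging pipelines, aimed at
people building vein-visualization or venipuncture-guidance systems:
it covers everything between a rectified NIR camera pair and the two
products such a system needs — the vein centerline (where the vessel
is) and the disparity map (how deep it is).

Hemoglobin absorbs NIR light, so veins appear as dark curvilinear
tubes on a brighter, noisy, unevenly lit background. The toolkit
implements:

- **Synthetic phantoms** — seeded generators for vein images with
  ground-truth masks and centerlines, stereo pairs from known integer
  disparity fields (forward warp, rightmost-wins occlusions), and a
  repetitive-texture stereo pair that is the standard failure case of
  local matching. Everything downstream is testable with no data
  downloads.
- **Preprocessing** — contrast-limited adaptive histogram
  equalization (clipped tile histograms, bilinear mapping
  interpolation) followed by median filtering.
- **Centerline extraction** — Hessian-eigenvalue vesselness for dark
  tubes, `V = exp(-R_b²/2β²)(1 - exp(-S²/2c²))` with `R_b = λ₁/λ₂`,
  `S = √(λ₁²+λ₂²)`, maximized over scales, thresholded, thinned to a
  1-px skeleton, then refined (small-component removal, spur pruning,
  endpoint gap joining).
- **Segmentation** — a U-Net whose encoder is the ResNet18 layout,
  with BYOL self-supervised pretraining of the encoder on unlabeled
  images and parameter transfer before supervised fine-tuning with
  binary cross-entropy. The whole network stack (conv/BN/pool/Adam
  with manual backprop) is float32 numpy and trains on one CPU at the
  desk-scale width.
- **Stereo matching** — the variable-weight AD-Census cost

      C(p,q) = α·ρ(C_AD, λ_AD) + (1-α)·ρ(C_C, λ_C),
      ρ(c, λ) = 1 - e^(-c/λ),   α = 1 - e^(-1/h_min),

  where `h_min` is the minimum cross-arm length of the pixel: edges
  (short arms) weight the absolute-difference term, homogeneous
  interiors (long arms) the census term. Cross arms follow either the
  classic single-tier rule (thresholds `τ`, `L`) or the two-tier rule
  (`τ₁, L₂` near, `τ₂, L₁` far, with a consecutive-pixel condition
  that stops arms at intensity edges). Costs are aggregated over the
  cross support regions with exact pixel counts, read out by
  winner-takes-all, and refined by a left-right consistency check.
- **Metrics** — BCE, IoU, Dice, boundary Hausdorff distance,
  disparity error rates, illuminance uniformity, and percent-change
  bookkeeping for method comparisons.

## Worked example

Match a synthetic stereo pair with known constant disparity 6 and
score the result:

```python
import numpy as np
from nirvein import phantom, stereo, metrics

left, right, gt, valid = phantom.make_stereo_pair(
    phantom.StereoPhantomSpec(
        base=phantom.PhantomSpec(height=64, width=96, seed=5, noise_sigma=0.01),
        disparity=6,
    )
)
est = stereo.match_pair(left, right, stereo.StereoParams(d_min=0, d_max=12))
mae, bad = metrics.disparity_error(est, gt, valid & np.isfinite(est))
print(f"mean abs error {mae:.3f} px, bad pixels (>2 px) {bad:.2f}%")
```

prints

```
mean abs error 0.000 px, bad pixels (>2 px) 0.00%
```

— the matcher recovers the constant disparity exactly on every valid
(non-occluded, in-frame) pixel; `bad` is the percentage of pixels off
by more than 2 px, the usual stereo evaluation convention.

The same flow is available from the shell:

```sh
nirvein phantom --out work/ph --stereo --disparity 6
nirvein stereo work/ph/left.png work/ph/right.png work/disp.pfm --dmax 12
nirvein eval stereo work/disp.pfm work/ph/gt_disparity.pfm
```

plus `preprocess`, `centerline`, `pretrain`, `train`, `segment` and
`pipeline` subcommands; `nirvein pipeline` runs the whole chain
(enhance → segment → centerline → match) and writes every
intermediate next to a resolved `config.yaml`.

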