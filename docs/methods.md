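# Methods

## Model

The segmenter is a two-stage cascade. Stage 1 is a residual U-Net over the
whole slice; stage 2 is a full-resolution network (FRN) over fixed-size ROI
windows centred on stage-1 candidates. The division of labour is explicit:
the coarse stage is trained to miss nothing (its loss weighs the
sensitivity term ten-fold), and the fine stage, seeing each candidate at
full resolution with surrounding context, restores precision by rejecting
mimics and tightening contours. Final masks are unions of per-ROI
segmentations, so background far from any candidate is structurally zero.

### Residual blocks

Both networks are assembled from residual units `out = f(h(x) + F(x))`
where `F` is conv3×3–BN–ReLU–conv3×3–BN, `h` the shortcut, and `f` a ReLU.
S1 keeps channels and resolution (`h` = identity); S2 adds a 1×1 projection
convolution (with BN) on the shortcut so channels and/or stride may change.
With the residual branch zeroed, a chain of S1 blocks is exactly the
identity on positive inputs and passes gradients undamped — the property
that motivates residual encoders for small-lesion work, and one the test
suite asserts literally.

### Coarse residual U-Net

Encoder: stage 1 is one conv-BN-ReLU producing 32 channels at full
resolution. Stage 2 holds 3 S1 blocks at 64 channels, stages 3 and 4 each
1 S2 (stride 2) + 3 S1 at 128/256 channels, stage 5 ends 2 S1 + 1 S2
(stride 2) at 512 channels. Decoder: ×2 bilinear interpolation (no learned
deconvolutions), concatenation with the same-resolution encoder feature,
two conv-BN-ReLU per stage, a 1×1 output convolution and a logistic output.
Inputs must be divisible by 16 (four halvings); anything else raises a
padding-required error rather than silently resizing.

Two compositional details are not fully determined by the architecture's
published description and were fixed as follows. Stage 2 contains only S1
blocks, which by definition cannot change channel count or resolution, yet
the encoder must halve resolution and double channels there; we insert a
2×2 max-pool + 1×1 conv-BN-ReLU transition at stage-2 entry, while stages
3–5 downsample inside their S2 blocks (stride 2). Stage 4's composition is
taken to mirror stage 3 (1×S2 + 3×S1), continuing the 32→64→128→256→512
doubling.

### R-ASPP and the FRN

The R-ASPP block computes

    f_ASPP   = K1 * ( Σᵢ K_dᵢ * f0 + AP(f0) )
    f_R-ASPP = f_ASPP + f0

with three dilated 3×3 convolutions (padding = dilation, so resolution is
preserved), a global-average-pooling branch broadcast over space, a 1×1
fusion convolution restoring the input channel count, and an identity
shortcut. With all kernels zero the block is exactly the identity. The
default dilation rates are (6, 8, 12); (4, 8, 12) is equally defensible and
both are exposed through `FrnSpec.dilation_rates` — the sources for this
design disagree internally, and we follow the more specific figure-level
statement.

The FRN is conv-in (3×3 → 32 channels) → 3×S1 → R-ASPP → 3×S1 → conv-out
(1×1 → 1) → logistic, with no pooling or striding anywhere: every feature
map lives at the ROI's native resolution, which is the point — at 32×32,
any downsampling throws away most of a 5-pixel lesion. Patches of 16, 32,
64 and 128 px are accepted; a patch not larger than the largest dilation
rate is rejected (for rate 12 that admits the 16 px ROI while refusing
degenerate inputs — a stricter "2×rate+1" minimum would contradict the
supported 16 px window, so the looser bound is deliberate).

Convolution weights are He-normal; batch norm follows every convolution
(the normalization scheme is otherwise unspecified); the output
nonlinearity is a logistic sigmoid, required for the probabilistic BCE.

## Losses

Per image, with ŷ clipped to [1e-7, 1−1e-7] for the logarithm:

* `L_BCE` — mean binary cross-entropy;
* `L_Dice = 1 − 2Σŷy/(Σŷ+Σy)` — overlap;
* `L_Sen = 1 − Σŷy/Σy` — the soft missed-diagnosis rate;
* `L_total = L_BCE + L_Dice + λ·L_Sen`, λ = 10 (coarse) or 1 (fine).

Batches average per-image losses (reporting elsewhere in the package is
also per image, so the conventions agree). When an image has no foreground
the Dice and sensitivity ratios get +1 smoothing on numerator and
denominator, making a correctly empty prediction cost zero; with any
foreground present the plain formulas apply, so the documented hand-worked
values hold exactly.

## Training protocol

Adam (β = 0.9/0.999, no weight decay), initial learning rate 2e-4, up to
500 epochs, batch size 6, early stopping on validation total loss
(patience 25 epochs, configurable; the monitored quantity and patience are
otherwise unspecified), five-fold cross-validation with seeded shuffled
partitions, best-validation weights restored. Channel widths divide by
`width_factor`, so desk-scale runs keep the exact topology.

Fine-stage training data are ROI crops: one positive per ground-truth
component, centred with ±4 px jitter; hard negatives centred on
false-positive components of the trained coarse stage, capped at one
negative per positive. This sampling rule is our design — it turns the
cascade's "reject the coarse stage's mistakes" intent into a training
signal.

Desk-scale runs in the test suite and the acceptance script use
`width_factor=8` (channels 4–64), 8 epochs per stage and a learning rate of
2e-3. At a few hundred optimizer steps the production rate of 2e-4 barely
moves the weights; 2e-3 converges stably at this scale. The single-image
memorization check goes further (5e-2): its purpose is to verify that the
optimization loop can drive the training loss to zero on one slice within
200 steps, which no production-scale step size can do; it is a smoke test
of the machinery, not a statement about the clinical protocol.

## Cascade inference

Coarse probability ≥ 0.5 → 8-connected components (area ≥ 1 px, both
configurable) → centroid-centred ROI, translated minimally to fit inside
the image (no padding, keeping the fine network's input statistics
uniform) → fine probability per ROI → fusion onto the slice canvas by
elementwise max (mean optional; max favours sensitivity) → threshold at
0.5 → pixels outside every ROI forced to background. Fusion happens before
thresholding; one ROI is taken per component even if the component exceeds
the window (possible at size 16) — a known limitation.

## Phantom generator

No clinical data ship with the package; the generator emulates the stated
appearance of the target domain:

* **background**: Gaussian noise smoothed with σ = 8 px, rescaled to mean
  0.55, SD 0.08, clipped to [0.25, 0.85] — a featureless textured
  mid-grey;
* **lesions**: anti-aliased filled ellipses (4×4 sub-pixel coverage,
  mask = coverage ≥ ½), darker than their surroundings by a contrast drawn
  from [0.25, 0.5]. Size is parameterized by *equivalent* diameter
  (default 2–7 mm, strictly below the 10 mm microbleed bound; 0.5 mm/px)
  so eccentricity (0–0.6) preserves area; placement is rejection-sampled
  so components never merge. These are the only structures in the mask;
* **mimics**: 0–2 thin dark random-walk curves per image (vein-like),
  darkening the image but absent from the mask;
* **noise**: additive Gaussian, SD 0.02 on the normalized scale.

Defaults (96×128 px, 1–3 lesions/image) are the desk-scale study
conditions. Everything is a pure function of (config, seed).

What the phantoms do *not* model: MR susceptibility physics (blooming,
phase effects), anatomy (ventricles, sulci, skull), intensity
inhomogeneity, calcifications with internal structure, or 3-D continuity of
veins across slices. Passing the desk-scale tests therefore demonstrates
that the cascade, losses, sampling and evaluation machinery work end to
end and that the two-stage design behaves as intended on data with this
geometry — not clinical-grade performance. Phantom scores (DSC ≈ 0.97 at
acceptance scale) are far above what heterogeneous clinical data yield.

Augmentation follows the stated stack: intensity `x·s + t` with
`s ~ U(0.8, 1.2)`, `t ~ U(−0.2, 0.2)` (the printed ±0.2 interval read as a
range), rotation up to 180° with probability 0.30 (bilinear for the image,
nearest-neighbour for the mask, zero padding), horizontal and vertical
flips each with probability 0.30, Gaussian noise (SD 0.02; the noise
distribution is otherwise unspecified). Min-max normalization maps constant
images to zeros rather than dividing by zero.

## Evaluation conventions

Metrics are computed per image and averaged (mean ± sample SD); a pooled
mode exists but is not the default — the ±SD presentation implies a
per-case distribution. If prediction and truth are both empty all metrics
are 1 (MCC 1); otherwise zero-denominator ratios are 0. Lesion matching
uses any-overlap (≥1 shared pixel) by default with an optional IoU
threshold; FP_avg is the per-image mean of unmatched predicted components.
The P-R curve pools pixels across images, evaluates at every distinct
threshold and integrates the step curve; it requires at least one positive
truth pixel. Cross-validation tables carry one row per fold (mean ± SD over
that fold's images) and a final row of the fold means (± SD of fold means).

## Numerical choices

* ŷ clipping 1e-7; Dice/Sen smoothing +1, engaged only on empty-foreground
  images; binarization is `≥ threshold`.
* ROI origin: `round(centroid) − size//2`, clamped; rounding is
  half-away-from-zero on the pixel grid.
* Batch norm ε = 1e-5, running-stat momentum 0.1 (eval mode uses running
  statistics).
* Float32 parameters by default; float64 available via the spec dtype for
  gradient verification.
* The autodiff engine recycles im2col scratch buffers through a pool and
  skips graph construction inside `no_grad()`; convolution backward is
  exact col2im scatter-add. ReLU uses the zero subgradient at the kink.
* Checkpoints store named arrays plus an architecture fingerprint and
  refuse to load into a mismatched spec.

## Known limitations

2-D only (no volumetric context); one ROI per candidate regardless of
component size; no test-time augmentation or multi-scale ensembling; BN
statistics are noisy for very small batches; the NumPy engine is CPU-bound
and single-threaded — at full width (width_factor 1) and 352×448 inputs it
is usable for inference but slow for training, which is why desk-scale
widths are the default in examples and scripts.
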