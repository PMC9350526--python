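# cmbcascade

Two-stage cascade segmentation of cerebral-microbleed-like micro-lesions in
SWI-like 2-D slices, with a built-in synthetic phantom generator, a joint
BCE + Dice + sensitivity loss, and a full pixel- and lesion-level evaluation
suite.

## The problem

Cerebral microbleeds (CMBs) are small ovoid hypointense foci — under 10 mm
in diameter — visible on susceptibility-weighted MRI (SWI). They matter
clinically (markers of small-vessel disease, amyloid angiopathy, stroke
risk), but they are tiny, scattered, and easily confused with veins,
calcifications and other dark structures; in practice a *missed* lesion is
far costlier than a spurious one. Single-shot segmentation of whole slices
struggles because lesion pixels are a vanishing fraction of the image.

`cmbcascade` implements a coarse-to-fine cascade built for exactly this
regime:

1. **Coarse stage** — a residual U-Net (encoder of S1/S2 residual blocks,
   bilinear-interpolation decoder, per-stage skip fusion) scans the whole
   slice and proposes candidate lesions. Its loss weighs sensitivity
   heavily (λ = 10) so that essentially nothing is missed.
2. **ROI extraction** — candidates are 8-connected components of the
   thresholded coarse probability map; a square window (16/32/64/128 px,
   default 32) is centred on each candidate centroid, shifted (never
   padded) to stay inside the image.
3. **Fine stage** — a full-resolution network (FRN: no downsampling
   anywhere) with a residual atrous spatial pyramid pooling block (R-ASPP,
   parallel dilated 3×3 convolutions at rates 6/8/12 plus global average
   pooling, fused by a 1×1 convolution over an identity shortcut)
   re-segments each ROI precisely (λ = 1), pruning the coarse stage's false
   positives. Per-ROI probabilities are fused back onto the slice
   (elementwise max) and thresholded; everything outside every ROI stays
   background.

### Losses

With per-pixel prediction ŷ and binary truth y over N pixels:

    L_BCE  = −(1/N) Σ [ yᵢ log ŷᵢ + (1−yᵢ) log(1−ŷᵢ) ]
    L_Dice = 1 − 2 Σ ŷᵢ yᵢ / (Σ ŷᵢ + Σ yᵢ)
    L_Sen  = 1 − Σ ŷᵢ yᵢ / Σ yᵢ          (a soft missed-diagnosis rate)
    L_total = L_BCE + L_Dice + λ · L_Sen

### Evaluation

Pixel level: SEN, PRE, DSC, F2 = 5·PRE·SEN/(4·PRE+SEN), JSC, MCC — computed
per image and averaged (mean ± SD). Lesion level: a true lesion counts as
detected iff a predicted component overlaps it; predicted components with
no overlap are false positives, reported as FP_avg per image. A pixel-wise
precision–recall curve gives the average precision (AP).

The networks run on a small NumPy reverse-mode autodiff engine included in
the package (`cmbcascade.autograd` / `cmbcascade.nn`: im2col convolution
with stride and dilation, fused batch norm, bilinear upsampling, Adam);
gradient correctness is pinned to central finite differences in the tests.

## Worked example

Phantom slices emulate the target domain: textured background, dark
elliptical lesions (the ground truth), and thin dark vein-like curves that
are *not* lesions — the classic false-positive bait.

```python
from cmbcascade import (PhantomConfig, generate_dataset, min_max_normalize,
                        CascadeSegmenter, metrics)

pairs = [(min_max_normalize(img), mask)
         for img, mask in generate_dataset(PhantomConfig(seed=42), 120)]
X = [img.pixels for img, _ in pairs]
y = [mask.labels for _, mask in pairs]

model = CascadeSegmenter(width_factor=8, coarse_epochs=6, fine_epochs=6,
                         learning_rate=2e-3, seed=0)
model.fit(X[:100], y[:100])

pred = model.predict(X[100:])
table = metrics.evaluate_pairs(pred, y[100:])
print(f"held-out mean DSC  {table['dsc'].mean():.3f}")
print(f"held-out mean SEN  {table['sen'].mean():.3f}")
print(f"false positives/image  {table['fp_components'].mean():.2f}")
```

Output:

```
held-out mean DSC  0.859
held-out mean SEN  0.942
false positives/image  0.75
```

DSC is the pixel overlap with the true masks on the 20 held-out slices, SEN
the fraction of true lesion pixels recovered, and the last line the mean
count of predicted lesion components that match no true lesion.
`CascadeSegmenter` follows the scikit-learn estimator contract
(`get_params`/`set_params`, `fit` returns `self`, fitted attributes such as
`coarse_model_` carry a trailing underscore), so it composes with sklearn
model-selection tooling.

A command-line interface covers the same workflows:

```sh
cmbcascade --seed 7 phantom --n 300 --out data/
cmbcascade --config cfg.yaml train-coarse --data data/ --out coarse.npz
cmbcascade --config cfg.yaml train-fine   --data data/ --out fine.npz
cmbcascade predict --image slice.nii.gz --coarse coarse.npz --fine fine.npz \
           --roi-size 32 --out mask.nii.gz
cmbcascade evaluate --pred preds/ --truth truths/ --out report/
```

## Layout

| module | contents |
|---|---|
| `cmbcascade.phantom` | synthetic slice/mask generator, min-max normalization, augmentation, 4:1 split |
| `cmbcascade.autograd`, `cmbcascade.nn` | NumPy autodiff engine, layers, Adam, checkpoints |
| `cmbcascade.nets` | residual U-Net, R-ASPP, FRN |
| `cmbcascade.losses` | BCE / Dice / sensitivity losses and the λ-weighted total |
| `cmbcascade.cascade` | thresholding, component extraction, ROI cropping, two-stage fusion |
| `cmbcascade.training` | Adam protocol, early stopping, 5-fold CV, fine-stage ROI sampling |
| `cmbcascade.metrics` | pixel metrics, lesion matching, FP_avg, P-R/AP |
| `cmbcascade.estimators` | sklearn-style `CoarseSegmenter`, `CascadeSegmenter` |
| `cmbcascade.io`, `cmbcascade.config`, `cmbcascade.cli` | NIfTI/PNG I/O, YAML config, CLI |

See `docs/methods.md` for the modelling choices, defaults and limitations.
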