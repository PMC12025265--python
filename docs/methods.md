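# Methods

## Problem and model

`spinebmd` estimates areal bone mineral density (BMD, g/cm²) of a single
vertebral body from one anteroposterior radiograph plus two physiological
covariates (body weight, vertebral bone area). The chain has three stages:

1. **Soft-tissue subtraction.** A U-Net is trained to predict the
   soft-tissue component of the radiograph; the bone-dominant image is
   `clamp(original − predicted_soft, 0, 1)`. This mimics what dual-energy
   absorptiometry achieves physically with two beam energies, using a
   learned model on a single-energy image instead. The network uses an
   input-anchored (residual) head: the 1×1 output convolution predicts
   the *deviation* from the input and the soft image is input − deviation,
   so the background is reproduced exactly wherever the head is silent —
   the residual-learning formulation standard in image restoration, which
   conditions plain-SGD optimization far better than regenerating the
   whole scene. Training pairs are augmented per epoch with random
   right-angle rotations and flips applied jointly to input and label.
2. **Regional grayscale features.** The vertebral ROI is partitioned by a
   3×3 grid into five regions (upper row, lower row, left / central /
   right middle cells). Per region the pixel values are clipped to three
   intervals around the region mean μ and standard deviation σ —
   `[μ−σ, μ+1.96σ]`, `[μ−1.96σ, μ+1.96σ]`, `[μ−1.96σ, μ+σ]` — and the
   clipped means, the raw region means, the whole-ROI mean and the two
   covariates form a 23-element feature vector.
3. **Bounded regression.** A fully connected network (23 → 32 → 16 → 8 → 1,
   ReLU hidden activations) with output activation
   `f(x) = 0.55·tanh(x) + 0.85` maps features to BMD. The head confines
   predictions to (0.3, 1.4) g/cm², a biologically plausible density range,
   whatever the training state. Data are split 80/20 train/validation;
   training is mini-batch SGD on the MSE with early stopping on validation
   loss, restoring the best-validation parameters.

Both networks are trained with plain stochastic gradient descent
(θ ← θ − η·∇J, no momentum, no weight decay) on the mean-squared-error
loss, implemented directly on NumPy arrays (im2col convolutions, manual
backpropagation). This keeps the update rule literal and the whole
experiment bit-reproducible from one integer seed.

## Synthetic phantoms

Clinical radiograph/DXA pairs are rarely shareable, so the package is
exercised end to end on phantoms with known ground truth:

- **Soft tissue**: three octaves of band-limited Gaussian noise, a lateral
  intensity gradient, soft-edged elliptical patches (organ overlap, bowel
  gas) and elongated soft bands crossing the frame (bowel loops, muscle
  margins, rib shadows). The patches and bands put nuisance energy at the
  spatial scale of the vertebra, which is what makes raw abdominal films
  hard to analyse region-by-region; the bands' coherent continuation
  across the frame is recoverable from context, which is what a
  convolutional model can exploit and a 23-number ROI summary cannot.
- **Bone**: a rounded-rectangle vertebral body (≈0.30×0.40 of the frame)
  with multi-scale trabecular texture. Mean in-mask attenuation is affine
  in the true density, `0.10 + 0.30·BMD`, and so is the texture contrast,
  sd = `0.015 + 0.045·BMD` — denser bone has more mineralized trabeculae
  and therefore higher local contrast. Carrying signal in both the level
  and the texture channel matters: the level channel is confounded with
  whatever background lies behind the vertebra, while the texture channel
  is what the σ-threshold features probe and what subtraction cleans.
  Four copies jittered in contrast (×0.95–1.05), brightness (±0.02) and
  tilt (±3°) are averaged into the bone layer; a random 0°/180° rotation
  and flip are applied (upright orientations only — a 90°-rotated
  vertebra would be anatomically implausible in an abdominal view and
  would transpose the ROI box).
- **Composite**: `input = clamp(soft + bone, 0, 1)` plus Gaussian noise
  (sd 0.01). The additive model is what makes subtraction the correct
  inverse operation.
- **Covariates**: weight = 40 + 25·BMD + N(0,4²) kg and
  area = 10 + 4·BMD + N(0,1²) cm², a linear-Gaussian stand-in for the
  observed correlation of weight and vertebral area with density. With BMD
  uniform on [0.35, 1.35] this gives analytic correlations of ≈0.87
  (weight) and ≈0.76 (area) with the target.

What the phantoms do **not** emulate: beam-hardening and scatter physics,
cortical/trabecular compartment structure, osteophytes and degenerative
morphology, pathology-driven texture change, inter-patient anatomy. A
passing phantom suite demonstrates that the pipeline recovers a known
density signal through the stated operations under realistic nuisance
structure — not clinical accuracy.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| image size | 128 px (cohort experiments use 64) | divisible by 2³ for the U-Net; 64 px keeps a 300-sample CPU experiment in minutes |
| BMD range | [0.35, 1.35] g/cm² | inside the regressor head's (0.3, 1.4) range with margin |
| noise sd | 0.01 | film-grain scale noise; small against the bone signal (~0.3) |
| U-Net depth / width | 3 / 16 channels | smallest net that resolves the band structures; widths double per level |
| U-Net η / epochs | 0.1 / 40 | plain SGD needs a large step: η=0.01 leaves the net barely better than the identity map within desk-scale epoch budgets; 40 epochs on 64 pairs reaches the subtraction quality plateau |
| ANN η / batch / patience | 0.05 / 8 / 50 epochs | selected by validation loss; the bounded head compresses gradients near the range edges, so overly small rates or patience stop the fit early |
| early-stop tolerance | 1e-5 | below the epoch-to-epoch validation noise floor |

## Numerical choices

- Images are float64 in [0, 1] internally (float32 inside the networks);
  8-bit PNG / 16-bit TIFF on disk, so quantization never interacts with
  the σ-thresholds during analysis.
- The U-Net's 1×1 output head is initialized at 0.1× the He scale so
  initial predictions sit near zero; at η=0.1 the first steps otherwise
  overshoot and training diverges.
- Max-pool backward routes gradient equally among tied maxima; ties are
  measure-zero in continuous data but occur in degenerate test fixtures.
- Grid boundaries of the 3×3 partition fall at `floor(i·n/3)`, giving an
  exact partition for any ROI ≥ 3×3; corner cells are absorbed into the
  upper and lower regions.
- The 80/20 split rounds the training share up (`ceil(0.8·n)`).
- Region μ and σ are computed on the raw (pre-clipping) pixels of the
  subtracted bone image; a σ of exactly zero makes clipping a no-op.
- `pearson_r` raises on zero-variance input instead of returning NaN.

## Design choices where the design was open

- **Composite operator** for the four jittered template variants:
  pixel-wise mean. It keeps intensities in range with no renormalization
  and makes the four-variant average a mild variance reduction on the
  jitter.
- **23-feature composition**: 15 clipped region means + 5 raw region
  means + 1 whole-ROI mean + weight + area. Only the total width is fixed
  by the architecture; this decomposition is the package's canonical
  reading and is pinned by tests.
- **Upsampling** by nearest-neighbor + 3×3 convolution rather than
  transposed convolution: no checkerboard artifacts at small image sizes
  and fewer parameters.
- **Output clamp** instead of a sigmoid on the U-Net head keeps the
  subtraction linear near the data range.
- **ROI selection**: phantoms use an interior analysis box inset 18% from
  the template's bounding box, the standard placement for vertebral
  texture ROIs — fully on trabecular bone, avoiding cortical margins and
  edge pixels under tilt jitter. No automatic vertebra detector is
  included; external images must bring a manual ROI rectangle.
- **Residual U-Net head and paired augmentation** (above) are the two
  training devices that make desk-scale plain-SGD subtraction usable.

## Problem sizes used by the test suite

The cohort-scale checks run one shared experiment: 300 phantoms at
64×64 px, U-Net trained on 64 pairs for 40 epochs, both pipeline arms
(raw vs subtracted) evaluated under an identical 240/60 split and
regressor seed. These sizes are the package's desk-scale reference
conditions; everything is configurable upward.

## Known limitations

- Plain SGD (kept deliberately) converges slowly; the U-Net epochs budget
  is the main quality lever for the subtracted arm.
- The bounded head biases predictions toward the center of its range when
  undertrained (targets near 0.3/1.4 need the largest pre-activations).
- Subtraction can only remove soft-tissue structure that is predictable
  from image context; background hidden entirely behind the vertebra is
  irreducible noise for raw and subtracted analysis alike.
- The feature extractor assumes an axis-aligned rectangular ROI.
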