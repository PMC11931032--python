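# Methods

## Problem and model

Blurred facial photographs — common in teledermatology, where patients
photograph their own skin — obscure the contours and small
high-contrast lesions (acne spots) that drive severity assessment.
`catdeblur` implements a three-stage enhancement framework:

1. **Contour accentuation (CAT).**  A deterministic preprocessor maps a
   color photo to a contour-emphasizing grayscale sketch:
   BT.601 luminance conversion
   `Gray = 0.299 R + 0.587 G + 0.114 B`, Gaussian *blending*
   (convolution with a normalized Gaussian kernel that smooths
   light/dark transitions while keeping facial structure), and gamma
   *contrast correction* `V_out = (V_in/255)^(1/γ) · 255`, with γ > 1
   for dark images and γ < 1 for light ones, chosen by mean luminance.
2. **Sketch deblurring (WGAN-GP).**  A residual encoder–decoder
   generator (64-filter 3×3 stem, two stride-2 stages with 128/256
   filters, nine residual blocks, two transposed-conv stages, 7×7
   output conv with Tanh) is trained against a convolutional critic
   (64/128/256/512 filters, 4×4 kernels, stride 2 except the last
   layer, LeakyReLU 0.2, batch norm momentum 0.999, scalar dense head)
   under the Wasserstein objective with gradient penalty:
   `L_D = −E D(real) + E D(fake) + λ E(‖∇D(x̂)‖₂ − 1)²` on uniform
   real/fake interpolates x̂, and `L_G = −E D(fake)`.
3. **Sketch-to-photo translation (cGAN).**  A bottleneck
   encoder–decoder generator (stride-2 4×4 encoder 64→512, nine 3×3
   residual blocks, transposed-conv decoder, 3-channel Tanh output) is
   trained against a pix2pix-style patch discriminator that sees the
   sketch concatenated with the photo.  The generator minimizes
   `L_total = λ_adv·L_adv + λ_ssi·(1 − SSIM)` with λ_adv = 0.8 and
   λ_ssi = 0.2; the adversarial term is the non-saturating
   binary-cross-entropy loss, evaluated on the mean patch logit.

All networks, losses and optimizers run on a small reverse-mode
automatic-differentiation engine written on numpy (`autodiff.py`,
`nn.py`).  The engine expresses each op's vector-Jacobian product in
terms of engine ops, so gradients are themselves differentiable; the
gradient-penalty term therefore contributes *exact* second-order
parameter gradients, verified against finite differences in the test
suite.

## Parameters that matter

| parameter | default | meaning / rationale |
| --- | --- | --- |
| CAT blending kernel | 7×7, σ = 2 px | visible smoothing without erasing contours at 64–256 px image scale |
| γ_dark / γ_light / threshold | 1.5 / 0.7 / 127.5 | dark images brighten, light images deepen; a mean exactly at threshold counts as light |
| `dodge_blend` | off | optional invert-and-divide sketch blend giving a line-drawing look; not part of the three canonical steps |
| degradation blur | 5×5 kernel, σ = 1 px | the evaluation protocol's Gaussian degradation; σ is configurable |
| train fraction | 0.70 | seeded shuffle, `|train| = round(0.7·N)` half-up |
| gradient-penalty weight λ | 10 | the standard WGAN-GP value; the penalty's interpolate distribution is uniform on real–fake segments |
| critic steps per generator step | 5 | WGAN convention |
| Adam | lr 2e-4, β₁ 0.5, β₂ 0.999 | the stated discriminator setup, also used for the generators |
| λ_adv / λ_ssi | 0.8 / 0.2 | fixed weighting of the translator objective |
| SSIM | 11×11 Gaussian window, σ 1.5, K₁ 0.01, K₂ 0.03, L 255 | the standard construction; population moments, valid-window mean |

## Synthetic fixtures

The clinical datasets behind the original study are not
redistributable, so the package generates face-like fixtures: a
skin-tone ellipse with mild vertical shading on a dark background,
darker strokes for jaw/eyes/nose/mouth (recorded in a ground-truth
contour mask) and `n_acne` small red-shifted disks placed disjointly
inside the face (recorded in an acne mask).  Every fixture is a pure
function of its seed.  The fixtures exercise exactly the structures the
framework claims to preserve — contours and small high-contrast
lesions — but they are *not* photorealistic: no pose/illumination
variation, no skin texture, no camera noise.  Passing tests therefore
demonstrate that the machinery is correct and that training moves the
metrics in the right direction at desk scale, not that clinical-grade
quality is reached on real photographs.

## Scaled-down study conditions

Full-scale GAN training is a GPU-week workload; the repository's
experiments run on one CPU in minutes.  The smoke-scale conditions
(`experiments.py`, used by the test suite and the acceptance script)
keep the paper-faithful topology, losses and optimizer but narrow the
networks and shorten the schedules:

* 64×64 fixtures, 16 training / 8 held-out faces, blur 5×5 σ = 1;
* deblurrer: 8/16/32 filters, 3 residual blocks, critic 8/16/32/64,
  320 generator steps, 5 critic steps per generator step,
  lr 5e-5 (G) / 2e-4 (D);
* translator: a single stride-2 encoder stage (32 filters) with the
  3×3 residual trunk at 32×32, 3 residual blocks, 1000 generator steps
  at lr 1e-3 (G) / 2e-4 (D), trained on the deblur stage's own output
  sketches so the translator sees its inference domain.  The shallow encoder preserves far more
  spatial detail per CPU step than the full-scale 4-stage bottleneck;
  it is the same architecture family with fewer stages.

Four deliberate departures from the full-scale defaults, all confined
to the smoke conditions and all standard GAN practice:

* **Critic normalization.**  Batch normalization inside a
  gradient-penalty critic couples the batch and destabilized the
  smoke runs (the penalty is defined per-sample); the smoke critic uses
  no normalization via the exposed `critic_norm` option.  The
  full-scale default keeps batch norm as specified.
* **Near-identity initialization + weight averaging.**  The deblur
  generator carries a global skip connection (DeblurGAN lineage) with a
  small-scale output-layer init, so the untrained network approximates
  the identity; inference uses an exponential moving average
  (decay 0.98) of the generator weights.  Both make the short
  Wasserstein schedule refine the input rather than re-synthesize it.
* **Slow generator.**  With only a few hundred steps, the deblur
  generator moves at lr 5e-5 against a 5-step critic so that the
  critic's transport direction (sharpening) dominates over drift.
* **Best-checkpoint selection.**  Adversarial training of the
  translator destabilizes after its reconstruction quality peaks; the
  returned generator is the EMA snapshot at the step where the
  smoothed *training-batch* SSI term was lowest.  No held-out data
  enters the selection.

## Numerical choices

* All classical image arithmetic is float64; quantization
  (round-half-up, clip to [0,255]) happens only at file output.
  Network arithmetic is float32.
* Gaussian kernels are sampled from the continuous density and
  renormalized to sum 1 (the 1/2πσ² prefactor cancels).
* Convolution borders: reflect padding for classical ops; zero padding
  inside networks.  Even-kernel same-size convolutions use asymmetric
  padding (total k−1).
* Gradient-penalty norm uses `sqrt(Σg² + 1e-12)`; a constant critic
  therefore scores the penalty as (10⁻⁶ − 1)² ≈ 1 rather than NaN.
* FID regularizes both covariance estimates with 1e-6·I and takes the
  real part of the matrix square root; BRISQUE/NIQE Mahalanobis
  distances use a pseudo-inverse with 1e-6·I jitter, so few-patch
  images degrade gracefully.
* AGGD/GGD shape parameters are fitted by moment matching over an
  α ∈ [0.2, 10] grid with step 10⁻³.
* Gamma selection ties (mean exactly at the threshold) go to "light";
  dataset split sizes round half-up.

## Metric battery caveats

FID and the Inception-score analogue canonically require a pretrained
classification network.  To stay self-contained the default
`FeatureExtractor` is a seeded random projection of per-image
standardized intensity + Laplacian channels, with a fixed softmax head
for the score.  These scores are deterministic and move in the right
direction under degradation (asserted by tests), but their absolute
values are comparable only within one extractor configuration — never
against published FID/IS numbers.  BRISQUE and NIQE use the standard
MSCN/AGGD feature constructions, scored against Gaussian models fitted
on the packaged clean fixtures rather than the original
human-opinion-calibrated models; the learned-IQA columns of the
evaluation table (DIQA SRCC/PLCC) require an externally trained
quality network and are reported as unavailable.

## Known limitations

* The deblurring stage trains with the Wasserstein objective alone (no
  content/perceptual loss), so paired alignment rests entirely on the
  global skip and the slow-generator schedule; at smoke scale the
  held-out SSIM gain over the blurred input is real but small.
* Smoke-scale translator outputs are structurally faithful but soft;
  several hundred CPU steps cannot reach the photographic detail a
  full-scale run would.
* The critic's dense head fixes the input resolution at build time;
  the generators accept any size divisible by their downsampling
  factor (4 for the deblurrer, 2^stages for the translator).
* `wasserstein_distance_1d` is the exact 1-D transport distance used
  for testing the training objective's concept; the critic itself
  estimates a high-dimensional analogue and the two are not
  interchangeable.
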