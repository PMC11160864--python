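# Methods

## Problem setting

Compact segmentation networks deployable on modest hardware lose
accuracy relative to large encoder–decoder models, and the loss is
worst for small, low-contrast targets such as kidney and liver tumors
in windowed CT. Knowledge distillation addresses this by training the
compact *student* to mimic a large pretrained *teacher*. The framework
implemented here moves knowledge selectively *backwards* through the
layer hierarchy instead of layer-to-same-layer or final-layer-only: the
teacher's middle layers teach the student's early layer, and the
teacher's final layer teaches the student's middle layers, at both the
feature level and the pixel level.

## The objective

Let `z_early, z_mid_j (j = 1..N), z_late` denote encoder activations
tapped at the first stage, the N intermediate stages and the last
stage, with superscripts `s` (student) and `t` (teacher). Let
`A(z)` denote the spatial attention operator: the stack `z` is
bilinearly resampled to a target spatial size, collapsed across
channels by `sum_c |z_c|^p` (default p = 1), flattened and
L2-normalized. The unified teacher middle representation `z_mid^t` is
the channel concatenation of all middle features after resampling each
to the smallest middle spatial size.

Feature-level terms (attention geometry):

* **UFD** = `|| A(z_early^s) − A(z_mid^t) ||_2`, student early features
  first resampled to the unified map's size.
* **IFD** = `Σ_j || A(z_mid_j^s) − A(z_late^t) ||_2` — a **sum** over
  student middle layers.

Each term is a distance between unit vectors, hence lies in [0, 2],
vanishes exactly when the two layers attend to the same locations, and
is invariant to positive rescaling of either feature map.

Pixel-level terms (per-pixel class distributions): the frozen teacher's
decoder emits a class-probability map at every decoder tap. The
unified middle predictive map `p_mid^t` is the per-pixel *average* of
the middle maps after resampling (averaging preserves the probability
simplex; concatenation would not). Student auxiliary maps come from
1×1 class-projection heads on the early and middle encoder taps,
spatially resampled to the teacher map's resolution and softmaxed.

* **UPD** = `KL(p_early^s || p_mid^t)`
* **IPD** = `(1/N) Σ_j KL(p_mid_j^s || p_late^t)` — a **mean** over
  layers, unlike IFD's sum.

KL is the natural-log pixel-wise divergence, averaged over pixels, with
1e-8 smoothing inside the log ratio, student distribution first (a
configuration switch provides the classic teacher-first direction).

The full training objective is

    L = L_seg + β·(UFD + IFD) + λ·(UPD + IPD),   β = 0.9, λ = 0.1,

where `L_seg` is the supervised focal-dice loss: focal cross-entropy
`−mean((1−p_true)^γ·log(p_true))` with γ = 2 plus soft dice
`1 − (2Σ p_fg·g + ε)/(Σ p_fg + Σ g + ε)` with ε = 1, summed with unit
weights. "Focal-dice" admits several compositions (sum, product,
focal-exponentiated dice); the sum is used because it is the most
common form and the choice does not interact with the distillation
machinery. After training, the teacher and all auxiliary heads are
discarded; the exported student contains only its encoder and
segmentation head.

## Reference networks

The teacher is a nested-skip encoder–decoder (UNet++-style) with one
deep-supervision head per decoder resolution; the student is a
residual-block encoder with a light bilinear-upsampling segmentation
head. Default widths are [8, 16, 32, 64] (≈75k parameters) and
[8, 16, 24, 32] (≈34k exported) — miniature analogues of the 36M/11M
networks used at full scale, sized so the entire study runs in minutes
on one CPU. Stage 0 keeps full resolution (the "early" tap); each
later stage halves it. "Early/middle/late" for a generic encoder is
read as first stage / all interior stages / last stage (default
N = 2). How a residual-encoder student should produce full-resolution
output is not dictated by the method; the bilinear-upsampling head is
an explicit design assumption of this package.

Teacher decoder taps for the predictive maps: the bottleneck head is
the early map, the intermediate nodes of the deepest decoding path the
middle maps, the full-resolution node the terminal map — one map per
resolution, mirroring the encoder taxonomy.

All parameters are He-normal initialised from a seeded generator; two
builds from the same seed are bit-identical.

## Numerical choices

* All computation is float64; the autodiff engine is a minimal
  reverse-mode tape over numpy written for this package (im2col
  convolution, matrix-form bilinear resampling, softmax algebra, Adam).
* Resampling is separable bilinear interpolation with half-pixel
  centres (constant-preserving); nearest-neighbour is available.
* Attention normalization divides by `max(||v||_2, 1e-8)`: an all-zero
  map yields the zero vector, so two zero maps give loss 0. A 1e-16
  constant inside `sqrt` keeps gradients finite at exact identity.
* The printed forms of the feature losses are typographically ambiguous
  (norms of normalized norms); they are implemented in the
  attention-transfer reading `|| v_s − v_t ||` with
  `v = vec(A(z))/||vec(A(z))||_2`, the only reading that is both scalar
  and consistent with channel normalization. L1 is available via
  configuration.
* Teacher middle-map attention is computed *after* concatenation, on
  the unified map, matching the single `A(z_mid^t)` term.
* Softmax temperature is fixed at 1 (configurable); no temperature is
  part of the method definition.
* Deep supervision during teacher pretraining scores each head at its
  native resolution against a nearest-downsampled mask (downsampling a
  binary mask by interpolation would create non-binary values); the
  per-head focal-dice losses are averaged.

## Synthetic phantoms

Real CT studies require large downloads and GPU training, so the
package ships a generator of 64×64 pseudo-CT slices: a textured
soft-tissue background (−100…−40 HU), one elliptical organ in its
organ-typical band (kidney 20–45 HU, liver 40–60 HU), and 0–3
hypodense tumor blobs with irregular radial-Fourier boundaries, plus
Gaussian pixel noise. Images are windowed with radiological standards
(kidney −200…300 HU, liver −40…160 HU) before entering a network.
Difficulty tiers set tumor/organ contrast and noise sd: easy 85/4,
medium 70/6, hard 55/8 (HU). The tiers were fixed during generator
design so that "hard" is the hardest setting at which the reference
teacher still reaches validation DSC ≥ 0.85 — low enough contrast that
the small no-distillation student visibly degrades, which is the regime
the method targets. With the default tumor-count distribution
(0.2, 0.4, 0.25, 0.15) about 80% of slices contain at least one tumor.

What the phantoms do *not* emulate: 3-D anatomy, organ-boundary
context, partial-volume effects, scanner artifacts, or KiTS/LiTS
intensity statistics. Passing results show the distillation machinery
is correct and directionally effective under controlled conditions;
they are not evidence about clinical data.

## Training protocol and study sizes

Adam (β₁ = 0.9, β₂ = 0.999), learning rate 1e-3 cosine-annealed per
epoch to 1e-6, batch size 8, random 90°-rotation/flip augmentation
(augmentations are restricted to the square's symmetries so masks stay
exactly binary; additive-noise augmentation is deliberately not used).
The packaged study uses 200 training and 50 validation hard kidney
phantoms, 20 teacher epochs and 12 student epochs — sizes chosen so the
whole two-arm, three-seed comparison completes in under a quarter hour
on a single CPU while leaving the teacher comfortably above its 0.85
validation-DSC gate.

Evaluation thresholds foreground probability at 0.5 and removes
predicted components under 20 pixels (the generator's smallest lesions
cover ≈80 pixels; sub-quarter-lesion components are treated as noise,
the usual minimum-lesion-size convention). The filter is applied
identically to every arm, so comparisons are unaffected. DSC is
computed per slice; two empty masks score 1. RVD keeps its sign per
sample and is undefined (excluded, counted) for empty ground truth;
cross-method comparison uses |RVD|. Results aggregate as mean ± std
over seeds {0, 1, 2} (offset by the study seed).

With β = λ = 0 the distillation trainer consumes the same RNG stream
and computes the same gradients as the plain supervised trainer, so the
two loss trajectories agree to floating-point equality — this reduction
is pinned by a test, as is gradient routing (every loss component alone
moves student parameters and never teacher parameters).

## Known limitations

* The comparison is directional (distilled ≥ plain student over three
  seeds), not a reproduction of full-scale benchmark numbers.
* The gap is seed-noisy at this scale. Both arms train for 12 epochs on
  200 slices with ~40k-parameter students, and individual runs of
  either arm can settle in a visibly worse basin (the distillation
  terms dominate the gradient early, which occasionally delays the
  supervised fit; plain supervised runs show their own failure seeds).
  Averaged over the packaged three-seed study the distilled arm wins
  (+0.08 DSC at the default data seed), but the sign of the mean gap
  can flip for other data seeds; `scripts/acceptance.py` reports
  whatever its `--seed` produces.
* Per-slice metrics; no volumetric aggregation.
* Binary segmentation only (background/tumor); the code paths accept
  K ≥ 2 classes but the phantom study never exercises K > 2.
* The miniature networks are not the full-scale architectures; widths
  are configurable but large configurations are untested and slow on
  CPU.
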