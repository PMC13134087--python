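# Methods

## The model

`lispcn` implements a multitask cycle-consistent adversarial network for
longitudinal breast DCE-MRI under neoadjuvant chemotherapy (NAC).  Two
generators translate between the pre-treatment and early-treatment image
domains: `G` maps a pre-NAC 3-channel stack (DCE series S0, S3, S5) to a
synthetic early-NAC stack, `F` maps back.  Each generator is an
encoder–decoder; the encoder is three stride-2 convolution stages with
channel widths 2, 4, 8, each followed by an efficient-channel-attention
(ECA) gate.  The encoder output is a spatial latent map `z` (8×8×8 for a
64×64 input) shared by two consumers: the decoder, which synthesizes the
other time point, and a classification head (global average pooling →
16-unit MLP → sigmoid) that predicts pathological complete response
(pCR).  Two Patch-GAN critics score local patches of each domain.

Training minimizes, for the generator side,

    L = adv(G) + adv(F) + λ_cyc · cycle + λ_cls · BCE + λ_pcp · pcp

with least-squares adversarial terms, an L1 cycle-consistency term
(`F(G(x)) ≈ x` and `G(F(y)) ≈ y`), class-weighted binary cross-entropy on
the head's output for the real pre-NAC latent, and a paired perceptual
term between `G(pre)` and the true early image (symmetrically for `F`).
Critics are trained on real batches versus a 50-image buffer of past
fakes.  Optimization is Adam(β₁=0.5, β₂=0.99), batch size 8, initial
learning rates 2·10⁻³ for the GAN components and 10⁻⁴ for the head, both
multiplied by 0.97 every 50 epochs.

### Numpy compute core

The package ships its own small reverse-mode autodiff and layer library
(`lispcn.nn`): tensors wrap numpy arrays, convolutions run as
shift-and-accumulate channel contractions (fast at these small channel
counts), and Adam with optional decoupled weight decay is included.  All
randomness flows from explicit `numpy` generators, so training runs are
bit-reproducible on a single CPU.  Backward closures receive the output
gradient as an argument rather than capturing the output tensor, keeping
computation graphs acyclic so they are freed by reference counting;
training holds well under 1 GB of memory.

### Architecture choices where the design was open

* **Residual generators.** The latent map of a 64×64 slice holds 512
  values — orders of magnitude too small to encode parenchyma texture.
  A decoder fed by `z` alone therefore cannot out-reconstruct the
  trivial copy-input baseline.  Generators use a global residual path,
  `out = clip(x + dec(z), −1, 1)`, with the decoder's output convolution
  initialized near zero so training starts at the identity map.
* **Skip connections.**  An oracle bound (ideal lesion edit rendered at
  the latent resolution, compared with the sharp ideal edit) shows that
  edits at 8×8 resolution score *below* the copy baseline on SSIM while
  sharp edits score above it.  The decoder therefore concatenates the
  encoder's intermediate activations after each upsampling stage
  (U-Net style) plus the full-resolution input before its output
  convolution — without that last skip the decoder only ever sees
  stride-2 features and cannot correct pixel-level acquisition noise.
  The classifier still reads only `z`.
* **Perceptual pyramid with a pixel stage.**  The frozen perceptual
  network is a seeded 3-stage random convolution pyramid (pretrained
  weights can be dropped in from an `.npz`; nothing is downloaded).  The
  pyramid's stage 0 is the image itself, so the first stage weight sets
  a plain L1 term.  Its minimizer under unpredictable acquisition noise
  is the noise-free target, so the paired term both edits and denoises.
* **Normalization.**  Instance normalization throughout generators and
  in all but the first critic block (cycle-GAN convention).  In the
  encoder it is also what keeps classification learning well
  conditioned: without it the shared representation fails to pick up
  the response signal within short iteration budgets on some seeds.
  Exposed as `ArchConfig.norm_encoder`.
* **ECA kernel and gate init.**  The adaptive rule `t = log2(C)/2 +
  1/2`, odd-rounded, floored at 3 — the floor prevents a degenerate
  size-1 kernel at the tiny widths used here.  The gating convolution
  is near-zero-initialized so gates open at 0.5; with larger random
  init the sigmoid gates can saturate shut before training starts,
  permanently silencing the latent map.

### Loss weights

The cycle weight follows the usual convention, λ_cyc = 10.  The paired
perceptual term is the analogue of the paired L1 term of pix2pix-style
training, conventionally weighted 10–100× the adversarial term; it is
set to λ_pcp = 50.  At small weights (1–10) the generator never commits
to the longitudinal edit — the adversarial and cycle terms are both
satisfied by the identity map, so only the paired term demands change.
λ_cls = 5 balances the classification gradient against the dense image
losses at the shared encoder.  All weights are exposed in
`LossWeights` and a zero disables its term exactly.  The trainer also
exposes an optional classification warm-up (`cls_warmup_iterations`,
off by default): the first iterations update encoder and head on the
classification loss alone before the joint adversarial phase.

## Ablation variants

* `AS-Dec` — decoder and both generative paths removed; a plain CNN
  classifier (encoder + head) trained with weighted BCE only.
* `AS-Dis` — critics removed; adversarial terms identically zero;
  reconstruction (cycle + perceptual) and classification kept.
* `AS-GF` — backward generator `F` removed; cycle term zero; paired
  translation with a single critic kept (pix2pix-like).
* `AS-Pcp` — λ_pcp = 0.

## Fine-tuning

Head-only fine-tuning (20 epochs, learning rate 5·10⁻⁶ by default)
updates exactly the classification head.  Each case contributes both its
real pre-NAC latent and the latent of its synthesized early-NAC image
`G(pre)`; the two are combined by a fixed averaging adapter
(`z = (Enc(pre) + Enc(G(pre)))/2`), equivalent to a frozen 1×1
concatenation adapter, so every non-head parameter stays bit-identical.

## The phantom generator

The phantom emulates the study's data-generating process at desk scale:

* **Parenchyma**: seeded Gaussian white noise smoothed at correlation
  length 4 px, rescaled to [−1, 0]; both time points share the texture
  field; acquisition noise (σ = 0.05) is independent per channel and
  time point.
* **Lesion**: an ellipse (semi-axes 6–9 px) adding positive contrast per
  channel with the enhancement ordering c_S0 < c_S3 (rise to peak) and a
  free S5 (plateau or washout).
* **Longitudinal change**: the early-NAC lesion is the same ellipse with
  semi-axes scaled by a shrinkage factor s ∈ (0, 1].
* **Response label**: Bernoulli with P(pCR) = σ(κ(s_ref − s)), κ = 12,
  s_ref = 0.7 — strong shrinkage makes response likely but the link is
  noisy.
* **Pre-visible response signal**: a latent responder propensity
  u ~ U(0, 1) drives peak enhancement (c_S3 = 0.30 + 0.65u), late
  washout (responders wash out), and shrinkage through a steep logistic
  map s(u) (bimodal: marked concentric shrinkage versus stable disease).
  The pivot of the map is calibrated by root-finding so the expected
  prevalence under the label link matches the target (default 20%,
  matching low clinical pCR rates).  Bimodality keeps most cases away
  from the link's noisy decision boundary; without it the Bayes-optimal
  AUC from pre-treatment images is only ≈ 0.76, with it ≈ 0.92.
* **Multi-slice patients**: biology (propensity, contrasts, shrinkage,
  label) is drawn once per patient; each patient contributes
  ``slices_per_patient`` 2-D slices (cohort default 3) — cross-sections
  of the lesion at offsets through the tumor on independent texture
  realizations, the way adjacent scanner slices decorrelate in texture
  while sharing the tumor's biology.  Multi-slice cohorts are what the
  patient-level split machinery is exercised on; the benchmark protocol
  below uses single-slice cases.

What the phantom does **not** model: pharmacokinetic enhancement curves,
scanner-specific artifacts, positional/elastic differences between time
points (a config flag exists for small translations but is off by
default), 3-D volumes, and non-elliptical lesion morphology.  Passing
the phantom benchmark therefore shows the pipeline is correct and the
training dynamics behave as designed — not that the model reaches any
particular performance on clinical data.

## Benchmark protocol

`lispcn.protocol.run_phantom_protocol` is the study design at phantom
scale: train on a seeded cohort of 200 phantom cases (one slice per
patient, prevalence 0.2, 64×64), 600 iterations at the published
optimizer settings, then evaluate on an *independently generated*
held-out cohort of 150 cases from a disjoint seed stream.  Slice
probabilities are averaged per patient before computing the AUC
(per-patient prediction — with single-slice cases this is the identity,
but the same code path serves multi-slice cohorts); image metrics
(SSIM/PSNR/LPIPS against the true early images, plus the copy-input
baseline) are per-slice.  A fresh evaluation cohort is used instead of
a 20% split because a 40-patient test split carries ±0.08 of AUC noise
— the ideal-feature oracle itself ranges 0.79–0.96 across such splits —
which would measure split luck rather than the model.  The iteration
budget (300–600 at desk scale; the protocol uses 600) and cohort sizes
were fixed as part of the study design.

## Evaluation machinery

* SSIM: Gaussian-window (11, σ=1.5) structural similarity, K1=0.01,
  K2=0.03, data range 1 after mapping [−1,1] → [0,1]; via scikit-image.
* PSNR: 10·log₁₀(1/MSE) on the unit scale; +∞ sentinel at MSE 0.
* Perceptual patch distance: unit-normalized channel features of the
  frozen pyramid, squared distance averaged over space and stages.
* Fréchet distance: Gaussian moments of pooled final-stage features,
  covariances regularized by 10⁻⁶·I, matrix square root via scipy;
  negative numerical residue clipped at zero.
* AUC: rank statistic (ties half credit), cross-checked in the tests
  against trapezoidal ROC integration; 95% CI by seeded case-level
  bootstrap (≥1000 resamples, degenerate resamples redrawn).
* Model comparison: paired permutation test on ΔAUC (case-wise score
  swaps).  Feature-distribution comparison: two-sided permutation test
  on the difference of means by default (Kolmogorov–Smirnov by flag),
  with ECDFs and kernel-density summaries on a shared grid.
* Grad-CAM++: closed-form channel weights from elementwise gradient
  powers at a chosen encoder stage (default: the penultimate stage —
  the 8×8 latent map is too coarse to localize lesion-scale structure),
  gradients taken at the pre-sigmoid logit, rectified weighted sum,
  bilinear upsampling, max-normalization.  Attention masks binarize at 50% of the
  peak by default (exposed flag); localization is scored by IoU against
  the lesion mask.

## Numerical / degenerate-input policy

Probabilities are clamped to [10⁻⁷, 1−10⁻⁷] with a warning before
log-loss; constant images normalize to all −1 with a warning; a
non-finite loss aborts training naming the offending term (never a
silent batch skip); both-empty masks score 1 by convention in Dice and
IoU; an all-zero attention gradient yields an all-zero heatmap with a
warning.

## Known limitations

The networks are deliberately tiny and the images 2-D and small; no
GPU path exists.  The phantom's response signal is by construction
visible in the pre-treatment image (enhancement, washout); on real
cohorts the strength of that association is an empirical question the
phantom cannot answer.  FID here uses the package's frozen random-conv
features, not Inception features, so its absolute values are not
comparable to published FID numbers.
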