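# Methods

`specseg` implements a multi-scale gated segmentation network for multiband
(multispectral / hyperspectral) images together with the surrounding
machinery — pairwise-CRF spatial refinement, adversarial domain adaptation,
contrastive self-supervision, anatomical knowledge regularization,
uncertainty calibration — and a synthetic phantom generator that makes the
whole pipeline testable on one CPU.  This note records the model, its
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## The model

An image is a raster `I ∈ R^{H×W×C}` with the band axis last.  The forward
pass has five stages.

1. **Convolutional pyramid.**  Level `l` computes
   `F_l = σ(W_l * F_{l-1} + b_l)` ('same'-padded cross-correlation, ReLU or
   leaky-ReLU).  Level 1 runs at full resolution; each subsequent level is
   downsampled by the stride schedule (default stride 2), so a 32×32 input
   with three scales yields 32/16/8 grids.
2. **Gated fusion.**  Each level is projected to a common width by a 1×1
   convolution, coarser levels are bilinearly upsampled (corner-aligned) to
   the finest grid, and the levels are combined as
   `F_multi = Σ_m α_m F_m` with `α = softmax(γ)` over one free scalar logit
   per scale.  The gate weights therefore always lie on the open simplex.
   The resampling rule (upsample-to-finest) is this package's choice; it
   preserves segmentation resolution.
3. **Spectral sequence encoding.**  Each pixel's band vector is treated as
   an ordered length-`C` sequence — neighbouring bands are correlated the
   way neighbouring time steps are, which is what motivates sequence models
   here.  Options: a bidirectional LSTM over bands (concatenated final
   hidden states), a transformer encoder (learned scalar embedding + band
   position codes, multi-head self-attention, mean-pooled), or `none`
   (bypass).  Both sequence encoders are order-sensitive by construction
   (verified by band-reversal tests); the bypass is order-equivariant.
   Neither recurrent nor attention encoding is claimed canonical; both are
   provided and configurable.  The per-pixel spectral features are
   concatenated with the fused spatial features.  This wiring — pyramid and
   sequence encoder in parallel, concatenated before attention — is the
   package's interpretation of the CNN + LSTM/transformer hybrid; the exact
   composition is the least constrained part of the architecture.
4. **Attention.**  `A = sigmoid(W_A * F + b_A)` (1×1 convolution), applied
   post-fusion; `F_att = A ⊙ F`.  The logistic sigmoid is used rather than
   ReLU so the gate is bounded in (0,1) and multiplication has
   soft-masking semantics.  The map is exportable as a raster for
   inspection.
5. **Heads.**  A 1×1-conv segmentation head with per-pixel softmax over `K`
   labels; a global-average-pooled linear classification head; and a linear
   projection head used only by the contrastive loss.  Argmax ties break
   toward the smallest class index, deterministically.

Everything runs on a small reverse-mode autodiff engine over NumPy arrays
(`specseg.autodiff`): dense tensors, broadcast arithmetic, batched matmul,
im2col convolution, the usual nonlinearities, and Adam.  Every operation's
gradient is validated against central differences in the test suite, and
backward closures capture arrays rather than tensors so graphs are
reference-acyclic and freed promptly.

## CRF spatial refinement

The label field follows the Gibbs distribution `P(Y) ∝ exp(-E(Y))` with

    E(Y) = Σ_i Φ_i(y_i) + Σ_{(i,j)∈N} Ψ(y_i, y_j)
    Ψ(y_i, y_j) = β₁‖F_i − F_j‖² + β₂·1[y_i ≠ y_j]

where `Φ_i = −log p_i` comes from the network's per-pixel probabilities and
each unordered neighbour pair is counted once.  Two readings in the source
material (a per-pixel conditional vs a global energy) are reconciled as the
standard global Gibbs form — the only reading consistent with a partition
function.  As written, the β₁ term does not depend on the labels, so MAP
labelings are provably invariant to β₁ (asserted in tests); a bilateral
variant `β₂·exp(−‖ΔF‖²/2σ²)·1[y_i≠y_j]`, in which feature contrast
modulates the coupling, is available behind a flag and off by default.

Inference:

* **Exact enumeration** for instances with `K^(H·W) ≤ 4096` — posterior
  table, partition value, marginals, exact MAP.  This is the oracle all
  approximate inference is tested against.
* **Mean field**: damped (0.5) row-major coordinate ascent on the fully
  factorized posterior.  Because the Potts compatibility is
  `β₂·1[k≠l]`, the pairwise message reduces to `β₂ Σ_j (1 − q_j(k))` and
  the label-free β₁ term cancels on normalization.  Mean field is a
  non-convex fixed-point iteration, so the sweeps run from `K+1`
  deterministic starts (the unary posterior plus one start biased toward
  each constant labeling) and the fixed point whose argmax labeling has the
  lowest energy is kept.
* **Approximate MAP** (`approximate_map`, used by `map_refine` above the
  enumeration bound): mean field, per-pixel argmax, then a deterministic
  first-improvement local search over single flips and adjacent pair
  flips.  The pair moves matter: on near-degenerate instances the
  factorized fixed point argmaxes to a labeling that differs from the MAP
  by two adjacent pixels and is single-flip stable, a failure mode that no
  amount of mean-field iteration, annealing, or restarting repairs (we
  traced it: the MAP labeling is not a stable fixed point of the factorized
  update there).  With polishing, the approximate MAP attains the exact MAP
  energy on 98–100 of 100 random 2×2 binary instances; each accepted move
  strictly lowers the energy, so the polish never worsens the mean-field
  result.

Default neighbourhood is 4-connected; `dense` (all pairs) is supported for
small images, with the dense message computed in closed form from the class
mass totals.  Per-pixel distributions remain normalized after every
mean-field update (each proposal is a softmax; a damped mixture of
normalized distributions is normalized).

## The objective

    L = L_seg + λ_cls·L_cls + λ_DA·L_DA + λ_CL·L_CL + λ_KR·L_KR + λ_UC·L_UC

with the adversarial coupling `min_θ max_φ L_DA + λ_adv·L_disc` trained by
alternating updates.  Term by term:

| term | form | default weight |
|---|---|---|
| `L_seg` | mean per-pixel cross-entropy | 1 (anchor) |
| `L_cls` | image-level cross-entropy | λ_cls = 1.0 |
| `L_DA` | mean pairwise squared distance between source and target pooled features | λ_DA = 1.0 |
| `L_disc` | mean log D(source) + mean log(1−D(target)); ≤ 0 | λ_adv = 0.1 |
| `L_CL` | normalized temperature-scaled contrastive loss, τ = 0.07 | λ_CL = 0.5 |
| `L_KR` | Σ pairs (d(c_i, c_j) − d_prior(i,j))² over soft centroids | λ_KR = 1.0 |
| `L_UC` | Brier-style calibration surrogate | λ_UC = 0.2 |

Notes on the open choices:

* **Squared distances.**  The feature-alignment penalty is read as
  *squared* Euclidean distance: differentiable everywhere and standard for
  moment alignment.  The plain-norm variant is a one-line change.
* **λ_cls.**  The composite supervised loss and the full objective are both
  honored by retaining the classification term in the total; no value is
  published, so λ_cls defaults to 1.
* **λ_adv = 0.1.**  No value is published.  At desk scale (batches of
  8–16, a freshly initialized two-layer MLP discriminator) the literal
  saturating min-max coupling at λ_adv = 1 oscillates: the encoder's
  adversarial gradient rivals the alignment gradient and can push the
  domains *apart*.  At 0.1 the explicit alignment term stays dominant and
  the adversarial pressure acts as a refinement.  λ_adv is an ordinary
  config field for users who want the balanced game.
* **L_UC.**  The uncertainty-calibration term has no published functional
  form.  The package uses the mean squared gap between per-pixel confidence
  (max probability) and the 0/1 correctness of the argmax — bounded in
  [0,1], differentiable through the gathered probability, and dependent
  only on quantities the model already produces.  This is an
  interpretation and is labeled as such wherever it is reported.
* **Contrastive denominator.**  The loss is implemented exactly as printed:
  for anchor i in view 1 the denominator runs over the B view-2 embeddings
  only (same-view negatives are not added, unlike some NT-Xent variants).
  The batch *sum* is returned, so identical embeddings give B·ln B
  (2·ln 2 at B = 2).
* **Probability clamping** at [1e-7, 1−1e-7] inside every logarithm;
  discriminator outputs at exactly 0/1 are clamped with a warning counter.
* Every term is ≥ 0 except the discriminator value, which is ≤ 0 by
  construction; the knowledge term is invariant to global translation of
  the centroids (it sees only distances).

## Training protocol

Adam (β = (0.9, 0.999), ε = 1e-8) with the published schedule: initial
learning rate 1e-4 decayed by 0.1 every 10 epochs, batch size 256, up to 50
epochs, early stopping at 5 consecutive non-improving validation epochs,
dropout 0.2, 80/10/10 train/val/test split.  The **desk preset**
(`TrainConfig.desk()`) keeps the schedule shape but overrides batch size to
16, the epoch budget to 15, and scales the learning rate by 100 (to 1e-2):
the desk-scale network has ~10⁴ parameters rather than ~10⁷·3.6, and at
1e-4 it would need far more than 15 epochs to converge.  Contrastive
pretraining is available as a separate phase (`pretrain_epochs`) or jointly
(`joint_contrastive`); whether the published model pretrained separately is
unstated, so both modes exist and the default is off.

Augmentations for the contrastive views: random crop (fraction range
0.8–1.0, bilinearly resized back), horizontal flip (p = 0.5), and spectral
jitter (per-band additive Gaussian, sd 0.05).  With all magnitudes zero the
augmentation is the identity, exactly.

Each epoch logs every objective term and the weighted total, which always
reproduces the weighted sum of the logged parts (audited in tests).  The
checkpoint stores the best-validation parameters, the architecture config,
and the seed; the JSON sidecar alone suffices to rebuild the architecture.
All randomness flows from one config seed through named NumPy substreams,
and execution is single-threaded, so fixed-seed reruns are bitwise
identical.

## The phantom generator

Phantoms emulate the *shape* of multiband medical data, not its physics:

* background pixels carry a flat spectrum at level 0.1;
* the lesion is a disc (radius uniform in 4–6 px on the default 32×32
  grid) whose spectrum is a Gaussian bump over the band index — centre
  `signature_centers[class]`, width 1.5 bands, amplitude 1.0 — so band
  order is meaningful and class identity is spectral, not spatial;
* optional anatomy discs at fixed positions on a ring carry their own
  bumps and define an exact anatomical prior (mean pairwise centroid
  distance) for the knowledge term;
* i.i.d. Gaussian noise, sd 0.1 (amplitude-to-noise ≈ 10, a comfortable
  but not trivial operating point for per-pixel spectral classification);
* the target domain applies a per-band affine shift (gain, offset) after
  noise — the simplest shift the alignment loss can provably reduce —
  and target masks are withheld from training interfaces while retained
  for evaluation.

Seeding: one master seed split via `SeedSequence(seed, spawn_key=(stream,
index))` with named streams geometry=0, spectra=1, noise=2; adding a stream
never perturbs the others.

What passing tests on phantoms do **not** show: robustness to anatomically
realistic shapes, partial-volume boundaries, modality physics (CT
calibration, MR sequences), spatially correlated noise, or 3-D lesions.
The phantom study validates the machinery — losses, inference, adaptation,
reproducibility — not clinical performance.

## Evaluation

* **Dice** on the lesion class (2|A∩B|/(|A|+|B|), defined as 1 when both
  masks are empty) and image-class accuracy.
* **RMSE / MAE / R² / MAPE** are computed on a declared surrogate: the
  per-image predicted lesion-area fraction vs the true fraction.  The
  regressed scalar behind the published figures is never defined, so this
  package states its own, and reports label it accordingly.  R² uses the
  truth-mean baseline; MAPE is on the percent scale and requires nonzero
  truths.
* **Wilcoxon signed-rank** (two-sided): exact null distribution of the
  positive-rank sum for n ≤ 25 via the generating-polynomial recursion
  (equivalent to enumerating all 2ⁿ sign vectors; mid-ranks doubled to stay
  integral), normal approximation with tie correction above.  Zero
  differences are discarded (Wilcoxon's original policy — the common
  statistical-package default); the two-sided p doubles the smaller tail
  and caps at 1.  The exact branch is cross-checked against an independent
  implementation in the tests.

## Problem sizes

The shipped studies are sized for a single CPU: the miniature end-to-end
study uses 200 phantoms of 32×32×8 (80/10/10) for up to 15 epochs
(~2–3 minutes); the domain-adaptation comparison uses 32+32 phantoms of
16×16×4 for 12 epochs per arm across three seeds; CRF checks run on 2×2
enumeration instances plus 8×8–16×16 mean-field grids.  The published-scale
preset (hidden 512, 8 heads, 2 transformer layers, batch 256, 512² images)
is configuration, not a tested path.

## Known limitations

* The NumPy engine is single-threaded and eager; it is sized for
  desk-scale studies, not for the published parameter counts.
* Dense-CRF support is quadratic in pixels (no permutohedral lattice) and
  capped at small images; the bilateral+dense combination skips the MAP
  polish.
* The anatomical prior construction (mean centroid distances from
  phantoms) is a stand-in for expert-defined priors, whose construction
  for real data is not described in the source material.
* DICOM is not read; convert to NIfTI first.  The NIfTI affine is carried
  opaquely and never interpreted.
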