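# Methods

## Problem setting

Low-dose CT (LDCT) denoising is posed as supervised image-to-image
translation: given aligned pairs (y, x) of low-dose and normal-dose slices,
learn G: y → x. The package implements the GAN formulation of this problem —
a residual-learning generator, a Wasserstein critic with gradient penalty,
and a four-term hybrid generator objective — plus everything needed to
exercise it without clinical data: a physics-based dose simulator, full
reference metrics (PSNR/SSIM/FSIM), and the training, ablation and
weight-sweep protocols.

## Dose simulator

CT noise originates in the projection domain. Each detector bin records a
photon count whose mean is I₀·e^(−p) (p the attenuation line integral, I₀
the unattenuated count per bin), plus additive electronic readout noise
𝒩(0, σ_e²). The simulator:

1. rasterizes an additive ellipse phantom on pixel centers of a uniform
   grid over [−1, 1]² (a pixel receives the summed attenuation of every
   ellipse containing its center);
2. forward-projects with the parallel-beam Radon transform at equispaced
   angles in [0, 180), line integrals in pixel-length units; the detector
   has ⌈N√2⌉ bins by default so the whole square sits inside the
   reconstruction circle;
3. rescales integrals by the pixel pitch 2/N to physical units (a
   unit-attenuation body ellipse then yields integrals of order 1–3, the
   regime where quantum noise matters), draws counts
   N = Poisson(I₀·e^(−p)) + 𝒩(0, σ_e²), clamps at one photon
   (photon-starvation guard — the simulator's declared dialect) and
   re-logs: p̂ = −ln(N/I₀);
4. reconstructs both the clean and the noisy sinogram by filtered
   back-projection (ramp/Shepp-Logan/Hann filters, cubic interpolation;
   cubic keeps the disk-phantom round-trip RMSE below 5 % of the
   attenuation scale at 180 angles, where linear interpolation sits at
   5.4 %).

NDCT is the FBP of the noiseless sinogram — not the phantom itself — so the
pair differs only by dose noise, not by reconstruction bias. All images of
a dataset are jointly min–max normalized to [0, 1] (per dataset, not per
image), and the declared `value_range` feeds every metric's data range.

**Noise realism.** Reconstructed noise is spatially correlated and
non-uniform: over 60 replicates at I₀ = 1e4 the center-to-edge variance
ratio inside a body phantom is ≈ 1.9, and variance falls monotonically with
dose — both are asserted by tests. The desk benchmark uses I₀ = 1e3, chosen
so the 64×64 phantom pairs sit near 28–32 dB PSNR, the fidelity regime
reported for clinical quarter-dose LDCT; at desk geometry (shorter ray
paths, fewer detector bins) a literal quarter of a clinical tube output
would produce unrealistically clean images. Features of real data the
simulator does not emulate: anatomical texture, beam hardening, scatter,
detector crosstalk, helical/cone-beam geometry. Passing tests therefore
demonstrate the method's mechanics and its response to dose physics, not
clinical performance.

## Networks

The generator follows the attention-guided denoising CNN family, 17 conv
layers on the main path: a sparse block (default 12 layers, dilation 2 on
every third layer — the dilation schedule is configurable and declared, not
claimed to match any published weight table), a feature-enhancement block
(3 layers) whose output is concatenated with the raw input image, a fusion
conv + a 1×1-conv sigmoid attention gate multiplied into the fused
features, and a reconstruction conv producing a noise map subtracted from
the input. Same-padding everywhere makes it fully convolutional and
size-agnostic. Zero-initializing the reconstruction conv makes the network
the exact identity at step 0; the desk profile uses this so training starts
from "return the noisy input" and any learning is pure improvement.

The critic is six stride-1 3×3 convolutions (64-64-128-128-256-256 at full
scale), ReLU, then FC 1024/512/1, unbounded output. It contains no
normalization layers: batch statistics would couple samples inside the
per-sample gradient penalty. The critic is built for one input size (the
patch size); full-image denoising uses only the generator.

At full scale the first FC layer holds 256·55²·1024 ≈ 7.9·10⁸ weights; the
architecture is only materialized at that size on machines with tens of GB
of memory. Desk configurations (8 channels everywhere, FC 128/64/1) run in
hundreds of MB.

## Autodiff engine

All networks and losses run on a package-local reverse-mode autodiff engine
over numpy (`ldctgan.autodiff`): a tape of ops whose vector-Jacobian
products are themselves expressed in the engine's primitives, so gradients
are differentiable and `grad(..., create_graph=True)` yields the exact
second-order derivatives the gradient-penalty term needs. Convolution is
im2col (strided-view gather in GEMM-major layout) followed by a single
BLAS matmul; the adjoint is overlap-add. The engine is float64 by default;
training profiles may select float32 (the desk profile does — the smoke
benchmark is insensitive to precision and roughly twice as fast). Verified
against central finite differences op-by-op and end-to-end, including a
double-backprop check of the penalty's parameter gradients at 1e-10
relative error.

## Losses

* **Adversarial (Wasserstein + gradient penalty).** Critic loss
  −E[D(x)] + E[D(G(y))] + λ·E[(‖∇_x̂D(x̂)‖−1)²] with x̂ = ε·x + (1−ε)·G(y),
  ε ~ U(0,1) per sample (the standard interpolation convention; the
  objective names x̂ but its construction is a design choice here).
  Generator side: −E[D(G(y))].
* **Perceptual.** (1/whd)·‖φ(G(y)) − φ(x)‖²_F. φ is pluggable: identity
  (reduces exactly to MSE — a tested identity), a seeded frozen random
  3-layer conv stack (the default: deterministic, download-free, and
  sufficient for every property the loss contract states), or a conv/pool
  stack loaded from a local NPZ of pretrained weights (e.g. a VGG-19
  export truncated at conv 16, grayscale replicated ×3 to RGB).
* **Sharpness.** MSE between local-sharpness maps. The default S is
  max-window gradient magnitude divided by (local intensity range +
  stabilizer 0.05), window radius 4, central differences with
  edge-replicated padding; the range window is one pixel wider than the
  gradient support so every gradient is normalized by the intensity
  variation that produced it. Dividing by local range is what makes the
  map sensitive in low-contrast regions. The operator is pluggable so a
  different sharpness detector can be dropped in.
* **SSIM.** Three-component form with C1 = (0.01L)², C2 = (0.03L)²,
  C3 = C2/2 (with that choice the product collapses to the standard
  two-term SSIM — kept as a regression test). Windowed mode (11×11
  Gaussian, σ = 1.5; matches scikit-image to 1e-6) is the default;
  global whole-image moments are available since the published
  description is ambiguous between the two. Loss: 1 − SSIM.
* **Hybrid.** α·L_adv + β·L_perc + γ·L_sharp + ω·L_SSIM with published
  defaults α = 0.005, β = 0.0995, γ = 0.95, ω = 0.95, λ = 10 (copied
  verbatim; they do not sum to 1 and no derivation exists to rationalize).
  Zero-weight terms are skipped entirely, which is what makes single-term
  ablations exact. The loss-weight container requires at least one
  positive generator weight.

## Metrics

PSNR = 10·log₁₀(L²/MSE), +∞ sentinel for identical images; the data range
L defaults to the dataset's declared value range (not per-image max) so
numbers are comparable across a report. FSIM follows the published
formulation: phase congruency from a 4-scale × 4-orientation log-Gabor
bank (min wavelength 6, scale factor 2, σ_onf 0.55, Rayleigh noise
compensation), Scharr gradient magnitude, similarity constants T1 = 0.85
and T2 = 160 on a 0–255 intensity convention, pooled with max phase
congruency as weight. One declared deviation: the gradient operator uses
symmetric boundary extension rather than zero fill, which makes FSIM
exactly invariant to a global intensity offset (zero fill leaks the offset
into border gradients). Images whose shorter side exceeds 256 are
average-pooled first.

## Training protocol

Per generator update the critic takes `critic_steps` updates (default 4 —
the alternation ratio is not pinned by the method description; the common
gradient-penalty convention is adopted). Adam (β = 0.9/0.999 — likewise a
convention default) at lr 1e-3 for phase 1 then 1e-4 for phase 2; the
published schedule is 100 + 100 epochs at batch 96 on 55×55 patches
(`paper` profile). The `desk` profile — 64×64 phantoms, 32×32 patches,
batch 16, 8-channel networks, 200 generator steps, float32 — runs the
identical code path in minutes. Patches are uniform-random aligned crops;
every stochastic choice (crops, batch order, ε draws, init) derives from
`TrainConfig.seed` through named substreams, so runs are bit-reproducible
and a run of k epochs followed by a resume of k more replays a single
2k-epoch run exactly. Validation metric for the best checkpoint: mean
held-out PSNR. Loss histories record the generator loss, the Wasserstein
estimate E[D(x)]−E[D(G(y))], the critic loss and each unweighted hybrid
term per step. Non-finite losses abort with the last-good checkpoint and a
diagnostic dump.

The ablation protocol trains one arm per loss term (that term's default
weight, all others zero) plus the full hybrid, and evaluates each on the
test split; the sweep protocol varies one weight over a grid with the
others fixed (coordinate-wise). Both are desk-scale reproductions of the
corresponding experimental procedure in shape; their absolute numbers are
properties of the synthetic benchmark only.

## Numerical choices and degenerate inputs

Counts are clamped at 1 photon before the log. SSIM variances are clamped
at 0 before the square root (cancellation guard). The gradient-penalty
norm uses a bare square root: exact at the tested closed forms; its
derivative is undefined only at exactly-zero critic gradients, which do
not occur for critics with nonzero weights. `sharpness_map` defines a
border of `radius` pixels as zero sharpness (the window is not fully
supported there). Max-pool ties share gradient equally. PSNR of identical
images returns +∞ rather than raising. FBP of an empty sinogram returns
zeros (linearity).

## Known limitations

The perceptual default is a random feature space, not a pretrained one;
with pretrained VGG weights available locally the published configuration
can be reproduced, but none of the package's own results depend on it.
The sharpness operator is a documented stand-in with the stated
low-contrast sensitivity property, not a re-derivation of any specific
published detector. Full-scale (512², batch 96, 200-epoch) training is
supported by the code path but far outside desk runtime; nothing in the
test suite exercises it.
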