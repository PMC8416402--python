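# ldctgan — low-dose CT denoising with a hybrid-loss Wasserstein GAN

Lowering the X-ray tube output of a CT scan protects the patient but floods
the reconstructed slices with quantum noise and streak artifacts, degrading
diagnostic quality. `ldctgan` implements a supervised denoising framework
that learns the mapping G: y → x from low-dose CT (LDCT) slices y to their
normal-dose counterparts (NDCT) x, together with a projection-domain dose
simulator so the entire method can be developed, trained and validated on
synthetic data at laptop scale — no clinical archives, GPUs or downloads
required.

It is aimed at medical-image-analysis researchers who want a transparent,
fully inspectable reference implementation of this family of methods: every
gradient in the package flows through a small, readable numpy autodiff
engine that ships with the code.

## The model

A generator G (a 17-layer attention-guided denoising CNN: sparse block with
mixed dilated/standard 3×3 convolutions → feature-enhancement block that
re-concatenates the network input → 1×1-convolution sigmoid attention gate →
reconstruction block that predicts a noise map n̂ and outputs y − n̂) is
trained against a Wasserstein critic D (six stride-1 3×3 convolutions, ReLU,
then fully-connected 1024 → 512 → 1) with the objective

    L_D = −E[D(x)] + E[D(G(y))] + λ·E[(‖∇_x̂ D(x̂)‖₂ − 1)²],   x̂ = ε·x + (1−ε)·G(y)

    L_G = α·(−E[D(G(y))]) + β·L_perc + γ·L_sharp + ω·(1 − SSIM(G(y), x))

where L_perc = (1/whd)·‖φ(G(y)) − φ(x)‖²_F is a feature-space (perceptual)
distance, L_sharp is the mean squared difference between local-sharpness
maps S(G(y)) and S(x), and SSIM is the three-component structural similarity
(2μₓμ_y+C1)/(μₓ²+μ_y²+C1) · (2σₓσ_y+C2)/(σₓ²+σ_y²+C2) · (σ_xy+C3)/(σₓσ_y+C3).
Default weights: α = 0.005, β = 0.0995, γ = 0.95, ω = 0.95, λ = 10.

The simulator builds ellipse phantoms, forward-projects them (parallel-beam
Radon transform), draws detector counts N = Poisson(I₀·e^(−p)) + 𝒩(0, σ_e²),
and reconstructs with filtered back-projection — producing the spatially
correlated, non-uniform image noise characteristic of real low-dose scans.

## Worked example

```python
import numpy as np
from ldctgan.phantom import build_dataset, DoseParams
from ldctgan.training import TrainConfig, desk_network_configs, train, denoise
from ldctgan.metrics import psnr

ds = build_dataset(16, 4, DoseParams(incident_photons=1e3), seed=1011, grid_size=64)
noisy = np.mean([psnr(ld.pixels, nd.pixels, 1.0) for nd, ld in ds.test])

gen_cfg, disc_cfg = desk_network_configs(channels=8)
res = train(ds, gen_cfg, disc_cfg, TrainConfig.desk_profile(seed=1))

den = np.mean([psnr(denoise(res.generator, ld).pixels, nd.pixels, 1.0)
               for nd, ld in ds.test])
print(f"noisy {noisy:.2f} dB -> denoised {den:.2f} dB")
```

This trains the desk profile (200 generator steps, 32×32 patches, batch 16,
four critic updates per generator update) in a few minutes on one CPU core
and prints

```
noisy 29.31 dB -> denoised 34.71 dB
```

— the held-out low-dose slices average 29.31 dB PSNR against their clean
counterparts before denoising and 34.71 dB after: the generator removed most
of the dose noise. (Gains of 5-6 dB are typical across seeds at this
setting.)

The same pipeline is available from the shell:

```bash
ldctgan simulate --n-train 16 --n-test 4 --size 64 --i0 1e3 --seed 7 --out data/
ldctgan train    --data data/ --out run/
ldctgan denoise  --ckpt run/generator_best.npz --in data/test_0000.npz --out den.npz
ldctgan metrics  --pred preds/ --ref refs/ --out report.csv
ldctgan ablate   --data data/ --out ablation/      # 5-arm loss ablation
ldctgan sweep    --data data/ --param beta --grid 0.01,0.0995,0.5 --out sweep/
```

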