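"""The four-term hybrid training objective.

The generator is trained against a weighted sum of

* an **adversarial** (Wasserstein) term, whose critic is regularized by a
  gradient penalty pushing the critic's input-gradient norm toward 1 at
  points interpolated between real and generated samples;
* a **perceptual** term — mean squared distance in the activation space of a
  fixed feature extractor phi (normalized by the feature volume w*h*d);
* a **sharpness** term — mean squared difference between local-sharpness
  maps of the generated and reference images;
* a **structural-similarity** term — 1 - SSIM, using the three-component
  (luminance * contrast * structure) form with stabilizers C1, C2, C3.

Critic objective:  -E[D(x)] + E[D(G(y))] + lambda * E[(||grad D(x_hat)|| - 1)^2].
Generator hybrid:  alpha*L_adv + beta*L_perc + gamma*L_sharp + omega*L_ssim,
with published defaults alpha=0.005, beta=0.0995, gamma=0.95, omega=0.95,
lambda=10.

All terms are differentiable through :mod:`ldctgan.autodiff`; the gradient
penalty relies on its double-backprop support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import he_init
from .phantom import CTImage


@dataclass
class LossWeights:
    """Weights of the hybrid objective (all nonnegative, at least one > 0)."""

    alpha: float = 0.005     # adversarial
    beta: float = 0.0995     # perceptual
    gamma: float = 0.95      # sharpness
    omega: float = 0.95      # SSIM
    gp_lambda: float = 10.0  # gradient-penalty coefficient

    def __post_init__(self):
        vals = (self.alpha, self.beta, self.gamma, self.omega, self.gp_lambda)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be nonnegative")
        if not any(v > 0 for v in (self.alpha, self.beta, self.gamma, self.omega)):
            raise ValueError("at least one generator loss weight must be positive")

    def masked(self, term: str) -> "LossWeights":
        """Single-term variant for ablations: keep one weight, zero the rest."""
        if term == "hybrid":
            return self
        keep = {"adversarial": "alpha", "perceptual": "beta",
                "sharpness": "gamma", "ssim": "omega"}
        if term not in keep:
            raise ValueError(f"unknown loss term {term!r}")
        kw = {k: 0.0 for k in ("alpha", "beta", "gamma", "omega")}
        kw[keep[term]] = getattr(self, keep[term]) or 1.0
        return LossWeights(gp_lambda=self.gp_lambda, **kw)


def _as_batch(x) -> Tensor:
    """Coerce CTImage / 2-D / 3-D / 4-D array-likes to a (B,1,H,W) tensor."""
    if isinstance(x, CTImage):
        x = x.pixels
    if isinstance(x, Tensor):
        t = x
    else:
        t = Tensor(np.asarray(x, dtype=np.float64))
    if t.ndim == 2:
        t = ad.reshape(t, (1, 1) + t.shape)
    elif t.ndim == 3:
        t = ad.reshape(t, (t.shape[0], 1) + t.shape[1:])
    elif t.ndim != 4:
        raise ValueError(f"expected 2-4 dims, got {t.ndim}")
    return t


# ---------------------------------------------------------------------------
# adversarial terms
# ---------------------------------------------------------------------------

def gradient_penalty(critic, real, fake, seed: int = 0) -> Tensor:
    """Mean over samples of (||grad_xhat D(xhat)||_2 - 1)^2 with
    xhat = eps*real + (1-eps)*fake, eps ~ U(0,1) per sample."""
    real, fake = _as_batch(real), _as_batch(fake)
    if real.shape != fake.shape:
        raise ValueError("real/fake batches must be shape-matched")
    b = real.shape[0]
    eps = np.random.default_rng(seed).uniform(size=(b, 1, 1, 1))
    xhat = Tensor(eps * real.data + (1.0 - eps) * fake.data, requires_grad=True)
    scores = critic(xhat)
    if not np.all(np.isfinite(scores.data)):
        raise FloatingPointError(
            f"critic produced non-finite scores (min={np.nanmin(scores.data)}, "
            f"max={np.nanmax(scores.data)})")
    g = ad.grad(ad.tsum(scores), xhat, create_graph=True)
    sq = ad.tsum(ad.mul(g, g), axis=(1, 2, 3))
    norms = ad.sqrt(sq)
    return ad.tmean(ad.pow_const(ad.sub(norms, Tensor(1.0)), 2.0))


def critic_loss(critic, real, fake, gp_lambda: float = 10.0, seed: int = 0) -> Tensor:
    """Wasserstein critic objective with gradient penalty."""
    real, fake = _as_batch(real), _as_batch(fake)
    wass = ad.add(ad.neg(ad.tmean(critic(real))), ad.tmean(critic(fake)))
    if gp_lambda == 0:
        return wass
    return ad.add(wass, ad.mul(Tensor(float(gp_lambda)),
                               gradient_penalty(critic, real, fake, seed=seed)))


def generator_adversarial_loss(critic, fake) -> Tensor:
    """-E[D(G(y))]: the generator pushes its outputs toward higher critic score."""
    return ad.neg(ad.tmean(critic(_as_batch(fake))))


# ---------------------------------------------------------------------------
# perceptual term
# ---------------------------------------------------------------------------

class FeatureExtractor:
    """Fixed (frozen) feature map phi for the perceptual loss.

    Descriptors:

    * ``identity`` — phi(x) = x, so the loss reduces to plain MSE;
    * ``seeded-random-conv-stack`` — a 3-layer random-weight ReLU conv stack
      (deterministic for a given seed), giving a nontrivial, download-free
      feature space;
    * ``vgg-npz`` — a conv/pool stack loaded from a local NPZ of pretrained
      weights (e.g. a VGG-19 export truncated at the 16th conv layer);
      grayscale inputs are replicated to three channels.
    """

    def __init__(self, descriptor: str = "seeded-random-conv-stack", seed: int = 0,
                 channels: tuple[int, ...] = (8, 16, 16), weights_path=None):
        if descriptor == "pretrained-vgg19-layer16":
            descriptor = "vgg-npz"
        self.descriptor = descriptor
        self.seed = seed
        self._layers: list[tuple[str, Tensor | None, Tensor | None]] = []
        if descriptor == "identity":
            self.expects_rgb = False
        elif descriptor == "seeded-random-conv-stack":
            self.expects_rgb = False
            rng = np.random.default_rng(seed)
            in_ch = 1
            for ch in channels:
                w = Tensor(he_init(rng, (ch, in_ch, 3, 3), in_ch * 9))
                b = Tensor(np.zeros(ch))
                self._layers.append(("conv_relu", w, b))
                in_ch = ch
        elif descriptor == "vgg-npz":
            self.expects_rgb = True
            if weights_path is None:
                raise ValueError("vgg-npz extractor requires weights_path")
            with np.load(weights_path) as z:
                layout = str(z["layout"]) if "layout" in z.files else None
                i = 0
                seq = layout if layout else "C" * sum(1 for k in z.files if k.endswith("_w"))
                for tok in seq:
                    if tok == "C":
                        w = Tensor(np.asarray(z[f"conv{i}_w"], dtype=np.float64))
                        b = Tensor(np.asarray(z[f"conv{i}_b"], dtype=np.float64))
                        self._layers.append(("conv_relu", w, b))
                        i += 1
                    elif tok == "P":
                        self._layers.append(("pool2", None, None))
        else:
            raise ValueError(f"unknown feature extractor {descriptor!r}")

    def __call__(self, x) -> Tensor:
        x = _as_batch(x)
        if self.expects_rgb and x.shape[1] == 1:
            x = ad.concat([x, x, x], axis=1)
        if self.descriptor == "identity":
            return x
        f = x
        for kind, w, b in self._layers:
            if kind == "conv_relu":
                f = ad.relu(ad.conv2d(f, w, b, pad=1))
            elif kind == "pool2":
                # 2x2 stride-2 average pool via strided slicing
                f = ad.mul(Tensor(0.25), ad.add(
                    ad.add(_stride2(f, 0, 0), _stride2(f, 0, 1)),
                    ad.add(_stride2(f, 1, 0), _stride2(f, 1, 1))))
        return f

    def output_dims(self, h: int, w: int) -> tuple[int, int, int]:
        probe = self(np.zeros((1, 1, h, w)))
        _, d, oh, ow = probe.shape
        return (ow, oh, d)


def _stride2(f: Tensor, oi: int, oj: int) -> Tensor:
    """Stride-2 subsample starting at offset (oi, oj), via gather."""
    b, c, h, w = f.shape
    rows = oi + 2 * np.arange(h // 2)
    cols = oj + 2 * np.arange(w // 2)
    idx = rows[:, None] * w + cols[None, :]
    flat = ad.reshape(f, (b * c, h * w))
    out = ad.take_ax1(flat, idx)
    return ad.reshape(out, (b, c, rows.size, cols.size))


def perceptual_loss(phi: FeatureExtractor, generated, reference) -> Tensor:
    """(1/(w*h*d)) * ||phi(G(y)) - phi(x)||_F^2, averaged over the batch."""
    fg = phi(generated)
    fr = phi(reference)
    if fg.shape != fr.shape:
        raise ValueError("feature volumes must be shape-matched")
    b = fg.shape[0]
    whd = fg.size // b
    diff = ad.sub(fg, fr)
    return ad.mul(Tensor(1.0 / whd), ad.tmean(ad.tsum(ad.mul(diff, diff), axis=(1, 2, 3))))


# ---------------------------------------------------------------------------
# sharpness term
# ---------------------------------------------------------------------------

@dataclass
class SharpnessConfig:
    """Local-sharpness operator: window max gradient magnitude divided by the
    local intensity range plus a stabilizer; maps into [0, 1].  Built to be
    strongly responsive in low-contrast regions (the local-range denominator
    rescales weak edges up)."""

    radius: int = 4
    stabilizer: float = 0.05
    operator: str = "central"   # central differences; "sobel" also accepted

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.stabilizer <= 0:
            raise ValueError("stabilizer must be > 0")
        if self.operator not in ("central", "sobel"):
            raise ValueError("operator must be 'central' or 'sobel'")


_KX_CENTRAL = np.array([[0, 0, 0], [-0.5, 0, 0.5], [0, 0, 0]])[None, None]
_KX_SOBEL = (np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]) / 8.0)[None, None]


def _gradient_magnitude(x: Tensor, operator: str) -> Tensor:
    # edge-replicated padding: a constant image has exactly zero gradient
    # everywhere, including the borders
    kx = _KX_CENTRAL if operator == "central" else _KX_SOBEL
    xp = ad.replicate_pad2d(x, 1)
    gx = ad.conv2d(xp, Tensor(kx))
    gy = ad.conv2d(xp, Tensor(np.swapaxes(kx, 2, 3).copy()))
    return ad.sqrt(ad.add(ad.mul(gx, gx), ad.mul(gy, gy)))


def sharpness_map_batch(x, cfg: SharpnessConfig | None = None) -> Tensor:
    """Differentiable local-sharpness map on a (B,1,H,W) batch.

    Interior pixels get max_window(|grad|) / (range_window(intensity) +
    stabilizer); a border of ``radius`` pixels (where the window is not fully
    supported) is defined as zero sharpness.
    """
    cfg = cfg or SharpnessConfig()
    x = _as_batch(x)
    b, _, h, w = x.shape
    r, k = cfg.radius, 2 * cfg.radius + 1
    if h < k or w < k:
        raise ValueError(f"image smaller than sharpness window ({k}x{k})")
    gm = _gradient_magnitude(x, cfg.operator)
    u_g = ad.unfold(gm, k, pad=0)                       # (B, k*k, L)
    max_g = ad.tmax_axis(u_g, axis=1)
    # the intensity-range window is one pixel wider than the gradient
    # support, so every gradient inside the window is normalized by the
    # intensity variation that produced it
    u_x = ad.unfold(ad.replicate_pad2d(x, 1), k + 2, pad=0)
    rng_x = ad.add(ad.tmax_axis(u_x, axis=1), ad.tmax_axis(ad.neg(u_x), axis=1))
    oh, ow = h - k + 1, w - k + 1
    core = ad.div(max_g, ad.add(rng_x, Tensor(float(cfg.stabilizer))))
    core = ad.clip01(ad.reshape(core, (b, 1, oh, ow)))
    return ad.pad_nd(core, [(0, 0), (0, 0), (r, r), (r, r)])


def sharpness_map(image: CTImage, cfg: SharpnessConfig | None = None) -> CTImage:
    """Grayscale local-sharpness map of a single image, values in [0, 1]."""
    out = sharpness_map_batch(image.pixels if isinstance(image, CTImage) else image, cfg)
    return CTImage(out.data[0, 0], value_range=(0.0, 1.0), meta={"sharpness": True})


def sharpness_loss(generated, reference, cfg: SharpnessConfig | None = None) -> Tensor:
    """MSE between the sharpness maps of the two images (symmetric)."""
    sg = sharpness_map_batch(generated, cfg)
    sr = sharpness_map_batch(reference, cfg)
    diff = ad.sub(sg, sr)
    return ad.tmean(ad.mul(diff, diff))


# ---------------------------------------------------------------------------
# structural similarity
# ---------------------------------------------------------------------------

@dataclass
class SSIMConfig:
    """SSIM stabilizers and mode.

    Defaults follow the standard choice C1=(0.01 L)^2, C2=(0.03 L)^2 with L
    the declared data range, and C3=C2/2 (which collapses the three-term
    product to the familiar two-term form).  ``windowed`` mode averages local
    SSIM over an 11x11 Gaussian (sigma 1.5) sliding window; ``global`` mode
    uses whole-image moments.
    """

    data_range: float = 1.0
    k1: float = 0.01
    k2: float = 0.03
    mode: str = "windowed"
    window: int = 11
    sigma: float = 1.5
    c3_ratio: float = 0.5    # C3 = c3_ratio * C2

    def __post_init__(self):
        if self.data_range <= 0:
            raise ValueError("data_range must be > 0")
        if self.window % 2 != 1:
            raise ValueError("window size must be odd")
        if self.mode not in ("windowed", "global"):
            raise ValueError("mode must be 'windowed' or 'global'")

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2

    @property
    def c3(self) -> float:
        return self.c3_ratio * self.c2


def _gaussian_kernel(window: int, sigma: float) -> np.ndarray:
    r = window // 2
    g = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
    g /= g.sum()
    return np.outer(g, g)[None, None]


def _ssim_terms(mu_x, mu_y, var_x, var_y, cov, cfg: SSIMConfig):
    c1, c2, c3 = cfg.c1, cfg.c2, cfg.c3
    var_x = ad.relu(var_x)   # guard tiny negative values from cancellation
    var_y = ad.relu(var_y)
    sd_x, sd_y = ad.sqrt(var_x), ad.sqrt(var_y)
    lum = ad.div(ad.add(ad.mul(Tensor(2.0), ad.mul(mu_x, mu_y)), Tensor(c1)),
                 ad.add(ad.add(ad.mul(mu_x, mu_x), ad.mul(mu_y, mu_y)), Tensor(c1)))
    con = ad.div(ad.add(ad.mul(Tensor(2.0), ad.mul(sd_x, sd_y)), Tensor(c2)),
                 ad.add(ad.add(var_x, var_y), Tensor(c2)))
    struct = ad.div(ad.add(cov, Tensor(c3)), ad.add(ad.mul(sd_x, sd_y), Tensor(c3)))
    return ad.mul(ad.mul(lum, con), struct)


def ssim_t(x, y, cfg: SSIMConfig | None = None) -> Tensor:
    """Differentiable SSIM (batch mean) as a scalar tensor."""
    cfg = cfg or SSIMConfig()
    x, y = _as_batch(x), _as_batch(y)
    if x.shape != y.shape:
        raise ValueError("SSIM inputs must be shape-matched")
    if cfg.mode == "global":
        mu_x = ad.tmean(x, axis=(1, 2, 3))
        mu_y = ad.tmean(y, axis=(1, 2, 3))
        dx = ad.sub(x, ad.reshape(mu_x, (x.shape[0], 1, 1, 1)))
        dy = ad.sub(y, ad.reshape(mu_y, (y.shape[0], 1, 1, 1)))
        var_x = ad.tmean(ad.mul(dx, dx), axis=(1, 2, 3))
        var_y = ad.tmean(ad.mul(dy, dy), axis=(1, 2, 3))
        cov = ad.tmean(ad.mul(dx, dy), axis=(1, 2, 3))
        s = _ssim_terms(mu_x, mu_y, var_x, var_y, cov, cfg)
        return ad.tmean(s)
    kern = Tensor(_gaussian_kernel(cfg.window, cfg.sigma))
    if x.shape[2] < cfg.window or x.shape[3] < cfg.window:
        raise ValueError("image smaller than SSIM window")
    mu_x = ad.conv2d(x, kern)
    mu_y = ad.conv2d(y, kern)
    mu_xx = ad.conv2d(ad.mul(x, x), kern)
    mu_yy = ad.conv2d(ad.mul(y, y), kern)
    mu_xy = ad.conv2d(ad.mul(x, y), kern)
    var_x = ad.sub(mu_xx, ad.mul(mu_x, mu_x))
    var_y = ad.sub(mu_yy, ad.mul(mu_y, mu_y))
    cov = ad.sub(mu_xy, ad.mul(mu_x, mu_y))
    s = _ssim_terms(mu_x, mu_y, var_x, var_y, cov, cfg)
    return ad.tmean(s)


def ssim(x, y, cfg: SSIMConfig | None = None) -> float:
    """SSIM in [-1, 1]; plain float for arrays or CTImages."""
    return float(ssim_t(x, y, cfg).data)


def ssim_loss(x, y, cfg: SSIMConfig | None = None) -> Tensor:
    """1 - SSIM(x, y); in [0, 2], differentiable end-to-end."""
    return ad.sub(Tensor(1.0), ssim_t(x, y, cfg))


# ---------------------------------------------------------------------------
# hybrid
# ---------------------------------------------------------------------------

def hybrid_loss(weights: LossWeights, critic, phi: FeatureExtractor,
                generated, reference,
                sharp_cfg: SharpnessConfig | None = None,
                ssim_cfg: SSIMConfig | None = None):
    """Weighted four-term generator objective.

    Returns (total loss tensor, breakdown dict); the breakdown carries each
    unweighted term plus an echo of the weights, for loss-curve logging.
    Terms with zero weight are skipped entirely (an ablation then literally
    never evaluates them).
    """
    generated, reference = _as_batch(generated), _as_batch(reference)
    total = Tensor(0.0)
    breakdown: dict[str, float] = {}
    if weights.alpha > 0:
        if critic is None:
            raise ValueError("adversarial weight > 0 requires a critic")
        l_adv = generator_adversarial_loss(critic, generated)
        total = ad.add(total, ad.mul(Tensor(weights.alpha), l_adv))
        breakdown["adversarial"] = float(l_adv.data)
    if weights.beta > 0:
        l_perc = perceptual_loss(phi, generated, reference)
        total = ad.add(total, ad.mul(Tensor(weights.beta), l_perc))
        breakdown["perceptual"] = float(l_perc.data)
    if weights.gamma > 0:
        l_sharp = sharpness_loss(generated, reference, sharp_cfg)
        total = ad.add(total, ad.mul(Tensor(weights.gamma), l_sharp))
        breakdown["sharpness"] = float(l_sharp.data)
    if weights.omega > 0:
        l_ssim = ssim_loss(generated, reference, ssim_cfg)
        total = ad.add(total, ad.mul(Tensor(weights.omega), l_ssim))
        breakdown["ssim"] = float(l_ssim.data)
    breakdown["weights"] = {"alpha": weights.alpha, "beta": weights.beta,
                            "gamma": weights.gamma, "omega": weights.omega,
                            "gp_lambda": weights.gp_lambda}
    return total, breakdown
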