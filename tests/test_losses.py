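"""Hybrid-loss components: exact identities, closed-form hand values,
cross-implementation SSIM checks, and finite-difference gradients."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity
from scipy.ndimage import gaussian_filter

from ldctgan import autodiff as ad
from ldctgan.autodiff import Tensor
from ldctgan import losses as L
from ldctgan.losses import (LossWeights, FeatureExtractor, SharpnessConfig,
                            SSIMConfig, gradient_penalty, critic_loss,
                            generator_adversarial_loss, perceptual_loss,
                            sharpness_map, sharpness_loss, ssim, ssim_loss,
                            hybrid_loss)
from ldctgan.networks import DiscriminatorConfig, build_discriminator


class ScaledSumCritic:
    """critic(v) = c * sum(v) / sqrt(n_pixels): input-gradient norm = c."""

    def __init__(self, c=1.0):
        self.c = c

    def __call__(self, v):
        n = v.size // v.shape[0]
        s = ad.tsum(v, axis=(1, 2, 3))
        return ad.reshape(ad.mul(Tensor(self.c / np.sqrt(n)), s), (v.shape[0], 1))


class ConstantCritic:
    def __init__(self, c=0.0):
        self.c = c

    def __call__(self, v):
        zero = ad.mul(Tensor(0.0), ad.tsum(v, axis=(1, 2, 3)))
        return ad.reshape(ad.add(zero, Tensor(self.c)), (v.shape[0], 1))


@pytest.fixture
def batch_pair(rng):
    real = rng.uniform(size=(4, 1, 8, 8))
    fake = rng.uniform(size=(4, 1, 8, 8))
    return real, fake


class TestGradientPenalty:
    def test_unit_gradient_linear_critic_gives_exact_zero(self, batch_pair):
        assert gradient_penalty(ScaledSumCritic(1.0), *batch_pair).item() == 0.0

    def test_constant_critic_gives_exact_one(self, batch_pair):
        assert gradient_penalty(ConstantCritic(), *batch_pair).item() == 1.0

    def test_doubled_gradient_gives_exact_one(self, batch_pair):
        assert gradient_penalty(ScaledSumCritic(2.0), *batch_pair).item() \
            == pytest.approx(1.0, abs=1e-12)

    def test_nonnegative_for_a_real_critic(self, batch_pair, rng):
        disc = build_discriminator(
            DiscriminatorConfig(conv_channels=[4, 4], fc_sizes=[8, 1]),
            input_size=8, seed=2)
        assert gradient_penalty(disc, *batch_pair, seed=5).item() >= 0.0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            gradient_penalty(ConstantCritic(), rng.uniform(size=(2, 1, 8, 8)),
                             rng.uniform(size=(2, 1, 6, 6)))


class TestCriticLoss:
    def test_zero_critic_zero_lambda_gives_zero(self, batch_pair):
        assert critic_loss(ConstantCritic(), *batch_pair, gp_lambda=0).item() == 0.0

    def test_hand_example_sum_critic(self):
        real = np.ones((1, 1, 4, 4))
        fake = np.zeros((1, 1, 4, 4))
        val = critic_loss(ScaledSumCritic(1.0), real, fake, gp_lambda=10.0)
        assert val.item() == pytest.approx(-4.0, abs=1e-12)

    def test_wasserstein_part_is_antisymmetric(self, batch_pair):
        real, fake = batch_pair
        critic = ScaledSumCritic(1.0)
        a = critic_loss(critic, real, fake, gp_lambda=0).item()
        b = critic_loss(critic, fake, real, gp_lambda=0).item()
        assert a == pytest.approx(-b, abs=1e-12)


class TestGeneratorAdversarialLoss:
    def test_constant_critic(self, batch_pair):
        assert generator_adversarial_loss(
            ConstantCritic(3.5), batch_pair[1]).item() == pytest.approx(-3.5)

    def test_hand_example(self):
        ones = np.ones((1, 1, 4, 4))
        assert generator_adversarial_loss(
            ScaledSumCritic(1.0), ones).item() == pytest.approx(-4.0)

    def test_decreases_as_critic_score_increases(self, batch_pair):
        lo = generator_adversarial_loss(ConstantCritic(1.0), batch_pair[1]).item()
        hi = generator_adversarial_loss(ConstantCritic(2.0), batch_pair[1]).item()
        assert hi < lo


class TestPerceptualLoss:
    def test_zero_at_identical_inputs(self, rng):
        phi = FeatureExtractor(seed=0)
        x = rng.uniform(size=(2, 1, 16, 16))
        assert perceptual_loss(phi, x, x).item() == 0.0

    def test_identity_extractor_equals_mse(self, rng):
        phi = FeatureExtractor("identity")
        x = rng.uniform(size=(3, 1, 10, 10))
        y = rng.uniform(size=(3, 1, 10, 10))
        mse = float(np.mean((x - y) ** 2))
        assert perceptual_loss(phi, x, y).item() == pytest.approx(mse, abs=1e-10)

    def test_seeded_random_stack_is_bit_reproducible(self, rng):
        x = rng.uniform(size=(2, 1, 12, 12))
        y = rng.uniform(size=(2, 1, 12, 12))
        a = perceptual_loss(FeatureExtractor(seed=42), x, y).item()
        b = perceptual_loss(FeatureExtractor(seed=42), x, y).item()
        assert a == b

    def test_output_dims_queryable(self):
        phi = FeatureExtractor(seed=0, channels=(4, 8))
        w, h, d = phi.output_dims(16, 16)
        assert (w, h, d) == (16, 16, 8)


class TestSharpness:
    def test_constant_image_gives_zero_map(self):
        out = sharpness_map(np.full((24, 24), 0.7), SharpnessConfig(radius=2))
        assert np.all(out.pixels == 0.0)

    def test_step_edge_is_maximal_on_the_edge(self):
        img = np.zeros((24, 24))
        img[:, 12:] = 1.0
        m = sharpness_map(img, SharpnessConfig(radius=2)).pixels
        interior = m[8:16]
        edge_val = interior[:, 11:13].max()
        far_val = interior[:, 4].max()
        # unit step, central differences: |grad| = 1/2, local range = 1,
        # so the edge plateau sits at 0.5/(1 + stabilizer)
        assert edge_val == pytest.approx(0.5 / 1.05, abs=1e-9)
        assert far_val < 0.05 * edge_val

    def test_blur_reduces_mean_sharpness(self, shepp_logan_96):
        cfg = SharpnessConfig(radius=3)
        sharp = sharpness_map(shepp_logan_96, cfg).pixels.mean()
        blurred = sharpness_map(gaussian_filter(shepp_logan_96, 2.0), cfg).pixels.mean()
        assert blurred < sharp

    def test_map_bounded_in_unit_interval(self, rng):
        m = sharpness_map(rng.uniform(size=(32, 32)), SharpnessConfig(radius=2))
        assert m.pixels.min() >= 0.0 and m.pixels.max() <= 1.0

    def test_loss_zero_positive_and_symmetric(self, shepp_logan_96):
        cfg = SharpnessConfig(radius=2)
        x = shepp_logan_96
        y = gaussian_filter(x, 2.0)
        assert sharpness_loss(x, x, cfg).item() == 0.0
        assert sharpness_loss(x, y, cfg).item() > 0.0
        assert sharpness_loss(x, y, cfg).item() == \
            pytest.approx(sharpness_loss(y, x, cfg).item(), rel=1e-12)


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        x = rng.uniform(size=(32, 32))
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-10)
        assert ssim(x, x, SSIMConfig(mode="global")) == pytest.approx(1.0, abs=1e-10)

    def test_global_mode_matches_hand_computed_moments(self, rng):
        # y = x + 0.2 with mu_x = 0.5, sigma_x = 0.5: contrast and structure
        # terms are exactly 1; luminance term from the printed closed form
        x = rng.normal(size=(16, 16))
        x = (x - x.mean()) / x.std() * 0.5 + 0.5
        y = x + 0.2
        c1 = (0.01 * 1.0) ** 2
        expect = (2 * 0.5 * 0.7 + c1) / (0.25 + 0.49 + c1)
        got = ssim(x, y, SSIMConfig(mode="global"))
        assert got == pytest.approx(expect, abs=1e-9)

    def test_windowed_matches_skimage_reference(self, rng):
        x = rng.uniform(size=(40, 40))
        y = np.clip(x + rng.normal(0, 0.08, x.shape), 0, 1)
        ref = structural_similarity(x, y, data_range=1.0, win_size=11,
                                    gaussian_weights=True, sigma=1.5,
                                    use_sample_covariance=False)
        assert ssim(x, y) == pytest.approx(ref, abs=1e-6)

    def test_symmetry(self, rng):
        x = rng.uniform(size=(24, 24))
        y = rng.uniform(size=(24, 24))
        assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-12)

    def test_c3_half_c2_collapses_to_two_term_form(self, rng):
        """With C3 = C2/2 the three-component product reduces to the
        familiar two-term SSIM; verified against that closed form."""
        for _ in range(3):
            x = rng.uniform(size=(20, 20))
            y = np.clip(x + rng.normal(0, 0.1, x.shape), 0, 1)
            cfg = SSIMConfig(mode="global")
            mu_x, mu_y = x.mean(), y.mean()
            vx, vy = x.var(), y.var()
            cov = ((x - mu_x) * (y - mu_y)).mean()
            c1, c2 = cfg.c1, cfg.c2
            two_term = ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) \
                / ((mu_x ** 2 + mu_y ** 2 + c1) * (vx + vy + c2))
            assert ssim(x, y, cfg) == pytest.approx(two_term, abs=1e-8)

    def test_anticorrelated_pair_loss_exceeds_one(self, rng):
        x = rng.uniform(size=(16, 16))
        y = 2 * x.mean() - x          # mirror around the shared mean
        val = ssim_loss(x, y, SSIMConfig(mode="global")).item()
        assert val > 1.0

    def test_loss_zero_at_equality_and_in_range(self, rng):
        x = rng.uniform(size=(16, 16))
        assert ssim_loss(x, x).item() == pytest.approx(0.0, abs=1e-10)


def _full_fd_gradient(fn, x, h=1e-6):
    g = np.zeros_like(x.data)
    it = np.nditer(x.data, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        x.data[idx] += h
        lp = fn().item()
        x.data[idx] -= 2 * h
        lm = fn().item()
        x.data[idx] += h
        g[idx] = (lp - lm) / (2 * h)
    return g


class TestLossGradients:
    """Central finite differences vs backprop on 8x8 probes, at 1e-4
    relative tolerance on the gradient vector."""

    @pytest.mark.parametrize("name", ["adversarial", "perceptual",
                                      "sharpness", "ssim_windowed",
                                      "ssim_global"])
    def test_loss_term_gradient(self, name, rng):
        gen = Tensor(rng.uniform(size=(1, 1, 8, 8)), requires_grad=True)
        ref = rng.uniform(size=(1, 1, 8, 8))
        if name == "adversarial":
            critic = build_discriminator(
                DiscriminatorConfig(conv_channels=[4, 4], fc_sizes=[8, 1]),
                input_size=8, seed=3)
            fn = lambda: generator_adversarial_loss(critic, gen)
        elif name == "perceptual":
            phi = FeatureExtractor(seed=1, channels=(4, 4))
            fn = lambda: perceptual_loss(phi, gen, ref)
        elif name == "sharpness":
            fn = lambda: sharpness_loss(gen, ref, SharpnessConfig(radius=2))
        elif name == "ssim_windowed":
            fn = lambda: ssim_loss(gen, ref, SSIMConfig(window=5))
        else:
            fn = lambda: ssim_loss(gen, ref, SSIMConfig(mode="global"))
        analytic = ad.grad(fn(), gen).data
        fd = _full_fd_gradient(fn, gen)
        denom = max(float(np.linalg.norm(fd)), 1e-12)
        assert np.linalg.norm(analytic - fd) / denom < 1e-4


class TestHybridLoss:
    def test_identical_inputs_and_zero_critic_give_zero(self, rng):
        x = rng.uniform(size=(2, 1, 16, 16))
        total, breakdown = hybrid_loss(
            LossWeights(), ConstantCritic(0.0), FeatureExtractor(seed=0),
            x, x, sharp_cfg=SharpnessConfig(radius=2),
            ssim_cfg=SSIMConfig(window=5))
        assert total.item() == pytest.approx(0.0, abs=1e-12)
        for term in ("perceptual", "sharpness", "ssim"):
            assert breakdown[term] == pytest.approx(0.0, abs=1e-12)

    def test_breakdown_echoes_published_default_weights(self, rng):
        x = rng.uniform(size=(1, 1, 16, 16))
        _, breakdown = hybrid_loss(
            LossWeights(), ConstantCritic(), FeatureExtractor(seed=0),
            x, x, sharp_cfg=SharpnessConfig(radius=2),
            ssim_cfg=SSIMConfig(window=5))
        assert breakdown["weights"] == {"alpha": 0.005, "beta": 0.0995,
                                        "gamma": 0.95, "omega": 0.95,
                                        "gp_lambda": 10.0}

    def test_weight_masking_for_ablations(self):
        w = LossWeights().masked("ssim")
        assert (w.alpha, w.beta, w.gamma) == (0.0, 0.0, 0.0)
        assert w.omega == 0.95
        assert LossWeights().masked("hybrid").alpha == 0.005

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=0, beta=0, gamma=0, omega=0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-0.1)
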