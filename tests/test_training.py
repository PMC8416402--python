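"""Patch extraction, the alternating optimization loop, inference, and the
ablation/sweep plumbing (kept at a few optimization steps; the full smoke
benchmark lives in the acceptance suite)."""

import numpy as np
import pytest

from ldctgan.losses import LossWeights
from ldctgan.networks import GeneratorConfig, save_checkpoint, build_generator
from ldctgan.phantom import CTImage
from ldctgan.training import (TrainConfig, PairedPatchSet, desk_network_configs,
                              extract_patches, train, resume_training, denoise,
                              ablation_run, weight_sweep, TrainState)


def quick_cfg(**over):
    base = dict(patch_size=16, patches_per_image=8, batch_size=8,
                epochs_phase1=1, epochs_phase2=0, max_generator_steps=2,
                seed=0)
    base.update(over)
    return TrainConfig.desk_profile(**base)


def small_nets():
    gen = GeneratorConfig(total_layers=6, base_channels=4,
                          zero_init_reconstruction=True)
    from ldctgan.networks import DiscriminatorConfig
    disc = DiscriminatorConfig(conv_channels=[4, 4], fc_sizes=[16, 1])
    return gen, disc


class TestExtractPatches:
    def test_counts_and_sizes(self, tiny_dataset):
        cfg = quick_cfg(patches_per_image=8, patch_size=16)
        ps = extract_patches(tiny_dataset, cfg)
        assert len(ps) == 8 * len(tiny_dataset.train)
        assert ps.ndct.shape[1:] == (1, 16, 16)
        assert ps.ldct.shape == ps.ndct.shape

    def test_alignment_via_marker_pixel(self, tiny_dataset):
        import copy
        ds = copy.deepcopy(tiny_dataset)
        nd, ld = ds.train[0]
        marked_nd = nd.pixels.copy()
        marked_ld = ld.pixels.copy()
        marked_nd[20, 30] = 7.0      # unique sentinel value
        marked_ld[20, 30] = 7.0
        ds.train[0] = (CTImage(marked_nd, value_range=(0, 8)),
                       CTImage(marked_ld, value_range=(0, 8)))
        ps = extract_patches(ds, quick_cfg(patches_per_image=64))
        found = 0
        for i in range(len(ps)):
            nd_hits = np.argwhere(ps.ndct[i, 0] == 7.0)
            ld_hits = np.argwhere(ps.ldct[i, 0] == 7.0)
            if len(nd_hits):
                found += 1
                assert np.array_equal(nd_hits, ld_hits)
        assert found > 0

    def test_same_seed_same_offsets(self, tiny_dataset):
        a = extract_patches(tiny_dataset, quick_cfg(seed=5))
        b = extract_patches(tiny_dataset, quick_cfg(seed=5))
        assert np.array_equal(a.offsets, b.offsets)

    def test_image_smaller_than_patch_named_in_error(self, tiny_dataset):
        with pytest.raises(ValueError, match="image 0"):
            extract_patches(tiny_dataset, quick_cfg(patch_size=100))


class TestTrainLoop:
    def test_zero_epoch_config_returns_valid_initial_state(self, tiny_dataset,
                                                           tmp_path):
        gen_cfg, disc_cfg = small_nets()
        cfg = quick_cfg(epochs_phase1=0, epochs_phase2=0,
                        max_generator_steps=None)
        res = train(tiny_dataset, gen_cfg, disc_cfg, cfg, out_dir=tmp_path)
        assert res.state.step == 0
        assert res.best_checkpoint is not None and res.best_checkpoint.exists()
        assert np.isfinite(res.state.best_val_psnr)

    def test_histories_record_every_step(self, tiny_dataset):
        gen_cfg, disc_cfg = small_nets()
        res = train(tiny_dataset, gen_cfg, disc_cfg,
                    quick_cfg(max_generator_steps=3))
        h = res.state.history
        assert len(h["generator_loss"]) == 3
        assert len(h["wasserstein"]) == 3
        assert len(h["critic_loss"]) == 3
        assert all(np.isfinite(h["generator_loss"]))

    def test_resume_matches_uninterrupted_run(self, tiny_dataset):
        gen_cfg, disc_cfg = small_nets()
        full = train(tiny_dataset, gen_cfg, disc_cfg,
                     quick_cfg(epochs_phase1=2, max_generator_steps=None))
        part = train(tiny_dataset, gen_cfg, disc_cfg,
                     quick_cfg(epochs_phase1=1, max_generator_steps=None))
        cont = resume_training(part, tiny_dataset,
                               quick_cfg(epochs_phase1=2, max_generator_steps=None))
        assert len(cont.state.history["generator_loss"]) == \
            len(full.state.history["generator_loss"])
        assert cont.state.config_echo == part.state.config_echo
        np.testing.assert_allclose(cont.state.history["generator_loss"],
                                   full.state.history["generator_loss"],
                                   rtol=1e-6)

    def test_resume_across_process_boundary_via_saved_runtime(self, tiny_dataset,
                                                              tmp_path):
        from ldctgan.training import save_training_runtime, load_training_runtime
        gen_cfg, disc_cfg = small_nets()
        full = train(tiny_dataset, gen_cfg, disc_cfg,
                     quick_cfg(epochs_phase1=2, max_generator_steps=None))
        part = train(tiny_dataset, gen_cfg, disc_cfg,
                     quick_cfg(epochs_phase1=1, max_generator_steps=None))
        path = tmp_path / "runtime.npz"
        save_training_runtime(part, path)
        restored = load_training_runtime(path, tiny_dataset,
                                         quick_cfg(epochs_phase1=1,
                                                   max_generator_steps=None))
        cont = resume_training(restored, tiny_dataset,
                               quick_cfg(epochs_phase1=2, max_generator_steps=None))
        np.testing.assert_allclose(cont.state.history["generator_loss"],
                                   full.state.history["generator_loss"],
                                   rtol=1e-6)

    def test_state_json_round_trip(self, tiny_dataset, tmp_path):
        gen_cfg, disc_cfg = small_nets()
        res = train(tiny_dataset, gen_cfg, disc_cfg,
                    quick_cfg(max_generator_steps=2), out_dir=tmp_path)
        loaded = TrainState.load(tmp_path / "train_state.json")
        assert loaded.step == res.state.step
        assert loaded.history["generator_loss"] == \
            pytest.approx(res.state.history["generator_loss"])
        assert (tmp_path / "loss_curves.csv").exists()


class TestDenoise:
    def test_zero_reconstruction_checkpoint_is_bitwise_identity(self, rng,
                                                                tmp_path):
        gen = build_generator(GeneratorConfig(
            total_layers=6, base_channels=4, zero_init_reconstruction=True),
            seed=0)
        path = tmp_path / "id.npz"
        save_checkpoint(gen, path)
        img = CTImage(rng.uniform(size=(40, 40)))
        out = denoise(path, img)
        assert np.array_equal(out.pixels, img.pixels)

    def test_output_shape_and_determinism(self, rng):
        gen = build_generator(GeneratorConfig(total_layers=6, base_channels=4),
                              seed=1)
        img = CTImage(rng.uniform(size=(96, 96)))
        a = denoise(gen, img)
        b = denoise(gen, img)
        assert a.pixels.shape == (96, 96)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.pixels.min() >= 0.0 and a.pixels.max() <= 1.0

    def test_corrupt_checkpoint_raises(self, tmp_path, rng):
        bad = tmp_path / "bad.npz"
        bad.write_bytes(b"junk")
        with pytest.raises(ValueError):
            denoise(bad, CTImage(rng.uniform(size=(32, 32))))


class TestAblationAndSweep:
    def test_hybrid_term_equals_full_weights(self):
        assert LossWeights().masked("hybrid") is not None
        w = LossWeights().masked("hybrid")
        assert (w.alpha, w.beta, w.gamma, w.omega) == (0.005, 0.0995, 0.95, 0.95)

    def test_single_arm_emits_report(self, tiny_dataset):
        gen_cfg, disc_cfg = small_nets()
        state, report = ablation_run(tiny_dataset, "ssim", gen_cfg, disc_cfg,
                                     quick_cfg(max_generator_steps=2))
        assert report.n_images == len(tiny_dataset.test)
        assert state.step == 2

    def test_unknown_term_rejected(self, tiny_dataset):
        gen_cfg, disc_cfg = small_nets()
        with pytest.raises(ValueError):
            ablation_run(tiny_dataset, "l2", gen_cfg, disc_cfg, quick_cfg())

    def test_sweep_rows_sorted_and_complete(self, tiny_dataset):
        gen_cfg, disc_cfg = small_nets()
        rows = weight_sweep(tiny_dataset, "beta", [0.5, 0.05],
                            gen_cfg, disc_cfg, quick_cfg(max_generator_steps=2))
        assert [r["value"] for r in rows] == [0.05, 0.5]
        assert all(np.isfinite(r["psnr_db_mean"]) for r in rows)

    def test_empty_grid_rejected(self, tiny_dataset):
        gen_cfg, disc_cfg = small_nets()
        with pytest.raises(ValueError):
            weight_sweep(tiny_dataset, "beta", [], gen_cfg, disc_cfg, quick_cfg())
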