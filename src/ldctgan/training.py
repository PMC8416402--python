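"""Patch extraction, alternating critic/generator optimization, inference.

Training follows the usual Wasserstein-GAN-with-gradient-penalty recipe:
per generator update the critic takes ``critic_steps`` updates on its own
objective, then the generator takes one step on the hybrid loss.  The
published schedule is Adam, mini-batch 96, learning rate 1e-3 for 100
epochs then 1e-4 for 100 more, on 55x55 aligned patches.  A ``desk``
profile (64x64 phantoms, 32x32 patches, batch 16, 8-channel networks, a few
hundred steps) exercises the identical code path at laptop cost.

Every stochastic choice — patch crops, batch order, gradient-penalty mixing
coefficients, parameter init — derives from ``TrainConfig.seed`` through
named substreams, so runs are exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Adam
from .networks import (GeneratorConfig, DiscriminatorConfig, Generator,
                       build_generator, build_discriminator,
                       save_checkpoint, load_checkpoint)
from .losses import (LossWeights, FeatureExtractor, SharpnessConfig, SSIMConfig,
                     critic_loss, hybrid_loss)
from .metrics import psnr, evaluate_pairs, MetricReport
from .phantom import CTImage, PairedDataset


@dataclass
class TrainConfig:
    patch_size: int = 55
    patches_per_image: int = 64
    batch_size: int = 96
    epochs_phase1: int = 100
    lr1: float = 1e-3
    epochs_phase2: int = 100
    lr2: float = 1e-4
    critic_steps: int = 4
    adam_betas: tuple[float, float] = (0.9, 0.999)
    weights: LossWeights = field(default_factory=LossWeights)
    sharp_cfg: SharpnessConfig = field(default_factory=SharpnessConfig)
    ssim_cfg: SSIMConfig = field(default_factory=SSIMConfig)
    extractor: str = "seeded-random-conv-stack"
    seed: int = 0
    max_generator_steps: int | None = None   # cap for smoke runs
    dtype: str = "float64"                   # engine precision for the run

    def __post_init__(self):
        if self.batch_size < 1 or self.patches_per_image < 1:
            raise ValueError("batch_size and patches_per_image must be >= 1")
        if self.lr1 <= 0 or self.lr2 <= 0:
            raise ValueError("learning rates must be > 0")
        if self.patch_size < 9:
            raise ValueError("patch_size below the receptive-field minimum")

    @classmethod
    def paper_profile(cls, **over) -> "TrainConfig":
        return cls(**over)

    @classmethod
    def desk_profile(cls, **over) -> "TrainConfig":
        """Small-everything profile running the full method in minutes."""
        base = dict(patch_size=32, patches_per_image=16, batch_size=16,
                    epochs_phase1=50, epochs_phase2=0, lr1=1e-3, lr2=1e-4,
                    critic_steps=4, max_generator_steps=200, dtype="float32")
        base.update(over)
        return cls(**base)


def desk_network_configs(channels: int = 8):
    """Uniform-width desk networks: every conv layer in both the generator
    and the critic carries ``channels`` channels."""
    gen = GeneratorConfig(total_layers=17, base_channels=channels,
                          zero_init_reconstruction=True)
    disc = DiscriminatorConfig(conv_channels=[channels] * 6,
                               fc_sizes=[128, 64, 1])
    return gen, disc


@dataclass
class PairedPatchSet:
    """Aligned NDCT/LDCT crops: both patches of a pair come from identical
    coordinates of the same source image pair."""

    ndct: np.ndarray          # (M, 1, p, p)
    ldct: np.ndarray
    source_index: np.ndarray  # (M,)
    offsets: np.ndarray       # (M, 2) row, col of top-left corner

    def __len__(self):
        return self.ndct.shape[0]


def extract_patches(ds: PairedDataset, cfg: TrainConfig) -> PairedPatchSet:
    """Uniform-random aligned crops: patches_per_image per training pair."""
    p = cfg.patch_size
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    nd_list, ld_list, src, offs = [], [], [], []
    for i, (nd, ld) in enumerate(ds.train):
        h, w = nd.pixels.shape
        if h < p or w < p:
            raise ValueError(f"image {i} ({h}x{w}) smaller than patch size {p}")
        for _ in range(cfg.patches_per_image):
            r = int(rng.integers(0, h - p + 1))
            c = int(rng.integers(0, w - p + 1))
            nd_list.append(nd.pixels[r:r + p, c:c + p])
            ld_list.append(ld.pixels[r:r + p, c:c + p])
            src.append(i)
            offs.append((r, c))
    return PairedPatchSet(
        ndct=np.stack(nd_list)[:, None], ldct=np.stack(ld_list)[:, None],
        source_index=np.asarray(src), offsets=np.asarray(offs))


@dataclass
class TrainState:
    """Loss histories (the three standard convergence curves: generator
    loss, Wasserstein-distance estimate, critic loss), step/epoch counters,
    best validation PSNR, and the config echo."""

    epoch: int = 0
    step: int = 0
    history: dict = field(default_factory=lambda: {
        "generator_loss": [], "wasserstein": [], "critic_loss": [],
        "adversarial": [], "perceptual": [], "sharpness": [], "ssim": []})
    val_psnr: list = field(default_factory=list)
    best_val_psnr: float = -np.inf
    config_echo: dict = field(default_factory=dict)
    aborted: str | None = None

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)

    @classmethod
    def load(cls, path) -> "TrainState":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass
class TrainResult:
    state: TrainState
    generator: Generator
    discriminator: object
    best_checkpoint: Path | None = None
    _runtime: dict | None = None      # optimizers, RNG streams etc. for resume


def _validation_psnr(gen: Generator, ds: PairedDataset) -> float:
    pairs = ds.test if ds.test else ds.train[:2]
    vals = []
    for nd, ld in pairs:
        den = denoise(gen, ld)
        vals.append(psnr(den.pixels, nd.pixels, data_range=1.0))
    finite = [v for v in vals if np.isfinite(v)]
    return float(np.mean(finite)) if finite else np.inf


def train(ds: PairedDataset, gen_cfg: GeneratorConfig, disc_cfg: DiscriminatorConfig,
          cfg: TrainConfig, out_dir=None, log_every: int = 1) -> TrainResult:
    """Run the alternating optimization; returns networks, loss histories
    and (if ``out_dir`` given) per-epoch + best-validation checkpoints.

    Aborts with the last-good checkpoint and a diagnostic dump if any loss
    turns non-finite.
    """
    with ad.default_dtype(cfg.dtype):
        return _train_impl(ds, gen_cfg, disc_cfg, cfg, out_dir, log_every)


def _train_impl(ds, gen_cfg, disc_cfg, cfg, out_dir, log_every) -> TrainResult:
    ss = np.random.SeedSequence([cfg.seed, 7])
    seeds = ss.generate_state(5)
    gen = build_generator(gen_cfg, seed=int(seeds[0] % 2**31))
    disc = build_discriminator(disc_cfg, cfg.patch_size, seed=int(seeds[1] % 2**31))
    phi = FeatureExtractor(cfg.extractor, seed=int(seeds[2] % 2**31))
    patches = extract_patches(ds, cfg)
    batch_rng = np.random.default_rng(int(seeds[3] % 2**31))
    gp_rng = np.random.default_rng(int(seeds[4] % 2**31))

    opt_g = Adam(gen.parameters(), lr=cfg.lr1, betas=cfg.adam_betas)
    opt_d = Adam(disc.parameters(), lr=cfg.lr1, betas=cfg.adam_betas)

    state = TrainState(config_echo={
        "train": {k: v for k, v in asdict(cfg).items()
                  if k not in ("weights", "sharp_cfg", "ssim_cfg")},
        "weights": asdict(cfg.weights),
        "generator": asdict(gen_cfg), "discriminator": asdict(disc_cfg)})

    runtime = {"gen": gen, "disc": disc, "phi": phi, "patches": patches,
               "batch_rng": batch_rng, "gp_rng": gp_rng,
               "opt_g": opt_g, "opt_d": opt_d}
    return _run_epochs(ds, cfg, state, runtime, out_dir, log_every,
                       start_epoch=0)


def resume_training(prev: TrainResult, ds: PairedDataset, cfg: TrainConfig,
                    out_dir=None, log_every: int = 1) -> TrainResult:
    """Continue a run from where it stopped, reusing its optimizers and RNG
    streams; training k epochs then resuming for k more reproduces a single
    2k-epoch run exactly."""
    if prev._runtime is None:
        raise ValueError("previous result carries no runtime; cannot resume")
    with ad.default_dtype(cfg.dtype):
        return _run_epochs(ds, cfg, prev.state, prev._runtime, out_dir, log_every,
                           start_epoch=prev.state.epoch)


def save_training_runtime(result: TrainResult, path) -> None:
    """Serialize everything a resume needs — network parameters, both Adam
    states, RNG stream states and the loss histories — into one archive."""
    rt = result._runtime
    if rt is None:
        raise ValueError("result carries no runtime")
    arrays = {}
    for prefix, model in (("gen", rt["gen"]), ("disc", rt["disc"])):
        for k, v in model.state_dict().items():
            arrays[f"{prefix}/{k}"] = v
    for prefix, opt in (("optg", rt["opt_g"]), ("optd", rt["opt_d"])):
        st = opt.state()
        for i, (m, v) in enumerate(zip(st["m"], st["v"])):
            arrays[f"{prefix}/m{i}"] = m
            arrays[f"{prefix}/v{i}"] = v
        arrays[f"{prefix}/t_lr"] = np.array([st["t"], st["lr"]])
    meta = {"state": asdict(result.state),
            "batch_rng": rt["batch_rng"].bit_generator.state,
            "gp_rng": rt["gp_rng"].bit_generator.state,
            "gen_cfg": asdict(rt["gen"].cfg),
            "disc_cfg": asdict(rt["disc"].cfg),
            "disc_input_size": rt["disc"].input_size,
            "phi": {"descriptor": rt["phi"].descriptor, "seed": rt["phi"].seed}}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_training_runtime(path, ds: PairedDataset, cfg: TrainConfig) -> TrainResult:
    """Rebuild a resumable TrainResult from :func:`save_training_runtime`
    output plus the (deterministically regenerable) dataset and config."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    with ad.default_dtype(cfg.dtype):
        gen = build_generator(GeneratorConfig(**meta["gen_cfg"]), seed=0)
        disc = build_discriminator(DiscriminatorConfig(**meta["disc_cfg"]),
                                   meta["disc_input_size"], seed=0)
        gen.load_state_dict({k[len("gen/"):]: v for k, v in arrays.items()
                             if k.startswith("gen/")})
        disc.load_state_dict({k[len("disc/"):]: v for k, v in arrays.items()
                              if k.startswith("disc/")})
        phi = FeatureExtractor(meta["phi"]["descriptor"], seed=meta["phi"]["seed"])
        patches = extract_patches(ds, cfg)
        opts = {}
        for prefix, model in (("optg", gen), ("optd", disc)):
            opt = Adam(model.parameters(), betas=cfg.adam_betas)
            n = len(opt.params)
            t, lr = arrays[f"{prefix}/t_lr"]
            opt.load_state({"t": t, "lr": lr,
                            "m": [arrays[f"{prefix}/m{i}"] for i in range(n)],
                            "v": [arrays[f"{prefix}/v{i}"] for i in range(n)]})
            opts[prefix] = opt
        batch_rng = np.random.default_rng()
        batch_rng.bit_generator.state = meta["batch_rng"]
        gp_rng = np.random.default_rng()
        gp_rng.bit_generator.state = meta["gp_rng"]
    state_d = meta["state"]
    state = TrainState(**state_d)
    runtime = {"gen": gen, "disc": disc, "phi": phi, "patches": patches,
               "batch_rng": batch_rng, "gp_rng": gp_rng,
               "opt_g": opts["optg"], "opt_d": opts["optd"]}
    return TrainResult(state, gen, disc, None, runtime)


def _run_epochs(ds, cfg, state, runtime, out_dir, log_every, start_epoch):
    gen, disc, phi = runtime["gen"], runtime["disc"], runtime["phi"]
    patches = runtime["patches"]
    batch_rng, gp_rng = runtime["batch_rng"], runtime["gp_rng"]
    opt_g, opt_d = runtime["opt_g"], runtime["opt_d"]

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    m = len(patches)
    steps_per_epoch = max(1, m // cfg.batch_size)
    total_epochs = cfg.epochs_phase1 + cfg.epochs_phase2
    best_ckpt = None

    def sample_batch():
        idx = batch_rng.choice(m, size=min(cfg.batch_size, m), replace=False)
        return patches.ndct[idx], patches.ldct[idx]

    def checkpoint(tag: str) -> Path | None:
        if out_dir is None:
            return None
        path = out_dir / f"generator_{tag}.npz"
        save_checkpoint(gen, path, extra={"epoch": state.epoch, "step": state.step})
        return path

    stop = False
    for epoch in range(start_epoch, total_epochs):
        lr = cfg.lr1 if epoch < cfg.epochs_phase1 else cfg.lr2
        opt_g.lr = opt_d.lr = lr
        for _ in range(steps_per_epoch):
            if cfg.max_generator_steps is not None and state.step >= cfg.max_generator_steps:
                stop = True
                break
            # critic updates
            c_loss_val = 0.0
            for _ in range(cfg.critic_steps):
                nd_b, ld_b = sample_batch()
                fake = gen(Tensor(ld_b)).detach()
                c_loss = critic_loss(disc, nd_b, fake.data,
                                     gp_lambda=cfg.weights.gp_lambda,
                                     seed=int(gp_rng.integers(2**31)))
                grads = ad.grad(c_loss, disc.parameters())
                opt_d.step(grads)
                c_loss_val = float(c_loss.data)
            w_val = float(np.mean(disc(Tensor(nd_b)).data)
                          - np.mean(disc(fake).data))
            # generator update
            nd_b, ld_b = sample_batch()
            fake = gen(Tensor(ld_b))
            g_loss, breakdown = hybrid_loss(cfg.weights, disc, phi, fake, nd_b,
                                            sharp_cfg=cfg.sharp_cfg,
                                            ssim_cfg=cfg.ssim_cfg)
            if not np.isfinite(g_loss.data) or not np.isfinite(c_loss_val):
                state.aborted = (f"non-finite loss at step {state.step}: "
                                 f"g={float(g_loss.data)}, c={c_loss_val}")
                if out_dir is not None:
                    checkpoint("abort")
                    (out_dir / "abort_diagnostics.json").write_text(
                        json.dumps({"reason": state.aborted,
                                    "breakdown": breakdown}, default=float))
                return TrainResult(state, gen, disc, best_ckpt, runtime)
            grads = ad.grad(g_loss, gen.parameters())
            opt_g.step(grads)

            state.step += 1
            if state.step % log_every == 0:
                h = state.history
                h["generator_loss"].append(float(g_loss.data))
                h["wasserstein"].append(w_val)
                h["critic_loss"].append(c_loss_val)
                for term in ("adversarial", "perceptual", "sharpness", "ssim"):
                    h[term].append(float(breakdown.get(term, np.nan)))
        state.epoch = epoch + 1
        val = _validation_psnr(gen, ds)
        state.val_psnr.append(val)
        checkpoint(f"epoch{state.epoch:03d}")
        if val > state.best_val_psnr:
            state.best_val_psnr = val
            best_ckpt = checkpoint("best")
        if stop:
            break
    if not state.val_psnr:                      # zero-epoch config
        state.best_val_psnr = _validation_psnr(gen, ds)
        best_ckpt = checkpoint("best")
    if out_dir is not None:
        state.save(out_dir / "train_state.json")
        _write_loss_csv(state, out_dir / "loss_curves.csv")
    return TrainResult(state, gen, disc, best_ckpt, runtime)


def _write_loss_csv(state: TrainState, path) -> None:
    import csv
    h = state.history
    keys = ["generator_loss", "wasserstein", "critic_loss",
            "adversarial", "perceptual", "sharpness", "ssim"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["step"] + keys)
        for i in range(len(h["generator_loss"])):
            w.writerow([i + 1] + [h[k][i] for k in keys])


def denoise(generator, image) -> CTImage:
    """Single full-image pass through the (size-agnostic) generator;
    output clipped to [0, 1].  ``generator`` may be a model or a
    checkpoint path."""
    if not isinstance(generator, Generator):
        generator = load_checkpoint(generator)
        if not isinstance(generator, Generator):
            raise ValueError("checkpoint does not contain a generator")
    pix = image.pixels if isinstance(image, CTImage) else np.asarray(image, dtype=np.float64)
    out = generator(Tensor(pix[None, None]))
    res = np.clip(out.data[0, 0], 0.0, 1.0)
    return CTImage(res, value_range=(0.0, 1.0), meta={"denoised": True})


# ---------------------------------------------------------------------------
# protocol reproductions: ablation and coordinate-wise weight sweep
# ---------------------------------------------------------------------------

ABLATION_TERMS = ("adversarial", "perceptual", "sharpness", "ssim", "hybrid")


def _evaluate_on_test(gen: Generator, ds: PairedDataset) -> MetricReport:
    pairs = [(denoise(gen, ld), nd) for nd, ld in (ds.test or ds.train)]
    return evaluate_pairs(pairs, data_range=1.0)


def ablation_run(ds: PairedDataset, term: str, gen_cfg: GeneratorConfig,
                 disc_cfg: DiscriminatorConfig, cfg: TrainConfig,
                 out_dir=None) -> tuple[TrainState, MetricReport]:
    """Train with a single loss term active (or the full hybrid) and
    evaluate on the test split — the loss-ablation protocol."""
    if term not in ABLATION_TERMS:
        raise ValueError(f"term must be one of {ABLATION_TERMS}")
    import copy
    run_cfg = copy.deepcopy(cfg)
    run_cfg.weights = cfg.weights.masked(term)
    res = train(ds, gen_cfg, disc_cfg, run_cfg, out_dir=out_dir)
    report = _evaluate_on_test(res.generator, ds)
    return res.state, report


def weight_sweep(ds: PairedDataset, parameter: str, grid, gen_cfg: GeneratorConfig,
                 disc_cfg: DiscriminatorConfig, cfg: TrainConfig) -> list[dict]:
    """Coordinate-wise sweep: vary one hybrid weight over ``grid`` with the
    others fixed; one train+evaluate per value.  Returns rows sorted by the
    swept value, each with mean PSNR/SSIM/FSIM and MSE."""
    if parameter not in ("alpha", "beta", "gamma", "omega"):
        raise ValueError("parameter must be one of alpha/beta/gamma/omega")
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("grid must be nonempty")
    import copy
    rows = []
    for value in grid:
        run_cfg = copy.deepcopy(cfg)
        setattr(run_cfg.weights, parameter, value)
        run_cfg.weights.__post_init__()
        res = train(ds, gen_cfg, disc_cfg, run_cfg)
        report = _evaluate_on_test(res.generator, ds)
        s = report.summary()
        finite_psnr = [p for p in report.psnr_db if np.isfinite(p)]
        mse = float(np.mean([10 ** (-p / 10) for p in finite_psnr])) if finite_psnr else 0.0
        rows.append({"parameter": parameter, "value": value,
                     "psnr_db_mean": s["psnr_db_mean"], "ssim_mean": s["ssim_mean"],
                     "fsim_mean": s["fsim_mean"], "mse": mse})
    return rows
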