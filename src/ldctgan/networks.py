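"""Generator and critic architectures.

The generator follows the attention-guided denoising CNN family (ADNet-style):
a 17-layer fully-convolutional network organized as

* **SB** (sparse block) — a stack of 3x3 convolutions mixing dilated and
  standard kernels, growing the receptive field cheaply;
* **FEB** (feature-enhancement block) — further convolutions whose output is
  concatenated with the raw network input, re-injecting global image
  information into the deep features;
* **AB** (attention block) — a 1x1 convolution + sigmoid gate computed from
  the concatenated volume and multiplied into the fused features, letting the
  network weight noise-bearing regions per pixel;
* **RB** (reconstruction block) — a final convolution producing a noise map
  that is subtracted from the input (residual noise learning), so the network
  output is ``input - predicted_noise``.

Every convolution is stride 1 with same-padding, making the generator
size-agnostic: any H x W image at least as large as one kernel is accepted.

The critic is the standard Wasserstein discriminator used for this task:
six stride-1 3x3 convolutions (channel ladder 64-64-128-128-256-256 at paper
scale), ReLU activations, then three fully-connected layers (1024, 512, 1)
ending in an unbounded scalar score.  No normalization layers are used in the
critic: per-sample gradient penalties interact badly with batch statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Module, Conv2d, Linear


@dataclass
class GeneratorConfig:
    """Width/depth knobs for the denoising generator.

    ``total_layers`` counts the convolutional layers on the main path
    (sparse block + feature enhancement + fusion + reconstruction); the
    attention gate's 1x1 convolution rides alongside.  ``dilation_schedule``
    (one integer per sparse-block layer) defaults to dilation 2 on every
    third layer, dilation 1 elsewhere.
    """

    total_layers: int = 17
    base_channels: int = 64
    dilation_schedule: list[int] | None = None
    zero_init_reconstruction: bool = False

    def __post_init__(self):
        if self.total_layers < 4:
            raise ValueError("total_layers must be >= 4 (one layer per block)")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        n_sb = self.n_sparse_layers
        if self.dilation_schedule is None:
            self.dilation_schedule = [2 if i % 3 == 1 else 1 for i in range(n_sb)]
        if len(self.dilation_schedule) != n_sb:
            raise ValueError(
                f"dilation_schedule length {len(self.dilation_schedule)} != "
                f"sparse-block depth {n_sb}")
        if any(d < 1 for d in self.dilation_schedule):
            raise ValueError("dilations must be >= 1")

    @property
    def n_feature_layers(self) -> int:
        return min(3, max(1, self.total_layers - 4))

    @property
    def n_sparse_layers(self) -> int:
        # main path: SB + FEB + fusion conv + reconstruction conv
        return self.total_layers - self.n_feature_layers - 2


@dataclass
class DiscriminatorConfig:
    """Critic layout: conv channel ladder then fully-connected head."""

    conv_channels: list[int] = field(default_factory=lambda: [64, 64, 128, 128, 256, 256])
    kernel: int = 3
    fc_sizes: list[int] = field(default_factory=lambda: [1024, 512, 1])

    def __post_init__(self):
        if not self.conv_channels or not self.fc_sizes:
            raise ValueError("conv_channels and fc_sizes must be nonempty")
        if self.fc_sizes[-1] != 1:
            raise ValueError("critic must end in a single scalar output")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd (same padding)")


class Generator(Module):
    def __init__(self, cfg: GeneratorConfig, seed: int):
        rng = np.random.default_rng(seed)
        c = cfg.base_channels
        self.cfg = cfg
        self.sparse = []
        in_ch = 1
        for d in cfg.dilation_schedule:
            self.sparse.append(Conv2d(in_ch, c, 3, rng, dilation=d))
            in_ch = c
        self.enhance = [Conv2d(c, c, 3, rng) for _ in range(cfg.n_feature_layers)]
        self.fuse = Conv2d(c + 1, c, 3, rng)
        self.attention = Conv2d(c + 1, c, 1, rng)
        self.reconstruction = Conv2d(c, 1, 3, rng,
                                     zero_init=cfg.zero_init_reconstruction)

    def forward(self, x: Tensor) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        f = x
        for conv in self.sparse:
            f = ad.relu(conv(f))
        for conv in self.enhance:
            f = ad.relu(conv(f))
        z = ad.concat([f, x], axis=1)            # re-inject global input info
        fused = ad.relu(self.fuse(z))
        gate = ad.sigmoid(self.attention(z))
        noise_map = self.reconstruction(ad.mul(gate, fused))
        return ad.sub(x, noise_map)


class Discriminator(Module):
    def __init__(self, cfg: DiscriminatorConfig, input_size: int, seed: int):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.input_size = int(input_size)
        self.convs = []
        in_ch = 1
        for ch in cfg.conv_channels:
            self.convs.append(Conv2d(in_ch, ch, cfg.kernel, rng))
            in_ch = ch
        self.flatten_size = in_ch * self.input_size ** 2
        self.fcs = []
        in_f = self.flatten_size
        for out_f in cfg.fc_sizes:
            self.fcs.append(Linear(in_f, out_f, rng))
            in_f = out_f

    def forward(self, x: Tensor) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        b, _, h, w = x.shape
        if h != self.input_size or w != self.input_size:
            raise ValueError(
                f"critic built for {self.input_size}x{self.input_size} inputs, got {h}x{w}")
        f = x
        for conv in self.convs:
            f = ad.relu(conv(f))
        f = ad.reshape(f, (b, self.flatten_size))
        for fc in self.fcs[:-1]:
            f = ad.relu(fc(f))
        return self.fcs[-1](f)                    # unbounded scalar per sample


def build_generator(cfg: GeneratorConfig, seed: int) -> Generator:
    return Generator(cfg, seed)


def build_discriminator(cfg: DiscriminatorConfig, input_size: int, seed: int) -> Discriminator:
    return Discriminator(cfg, input_size, seed)


def parameter_count(model: Module) -> int:
    return model.parameter_count()


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def _config_payload(model: Module) -> dict:
    if isinstance(model, Generator):
        return {"kind": "generator", "config": asdict(model.cfg)}
    if isinstance(model, Discriminator):
        return {"kind": "discriminator", "config": asdict(model.cfg),
                "input_size": model.input_size}
    raise TypeError(f"cannot checkpoint {type(model).__name__}")


def save_checkpoint(model: Module, path, extra: dict | None = None) -> None:
    """Single-archive checkpoint: config echo + named float64 parameter
    arrays.  Round trips are bit-exact."""
    payload = _config_payload(model)
    if extra:
        payload["extra"] = extra
    arrays = {"param/" + k: v for k, v in model.state_dict().items()}
    np.savez(path, __config__=np.frombuffer(
        json.dumps(payload).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> Module:
    try:
        with np.load(path) as z:
            payload = json.loads(bytes(z["__config__"]).decode())
            state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    except (OSError, ValueError, KeyError, json.JSONDecodeError) as e:
        raise ValueError(f"corrupt or unreadable checkpoint: {path}: {e}") from e
    if payload["kind"] == "generator":
        model = Generator(GeneratorConfig(**payload["config"]), seed=0)
    elif payload["kind"] == "discriminator":
        model = Discriminator(DiscriminatorConfig(**payload["config"]),
                              payload["input_size"], seed=0)
    else:
        raise ValueError(f"unknown checkpoint kind {payload['kind']!r}")
    model.load_state_dict(state)
    return model
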