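"""Layers, parameter containers, initialization and the Adam optimizer.

Thin object layer over :mod:`ldctgan.autodiff`.  Parameters are leaf tensors
with ``requires_grad=True``; modules expose ``named_parameters`` for the
optimizer and for bit-exact checkpointing.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: child modules and parameters are discovered by attribute
    inspection, in definition order (stable for checkpoints)."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield (prefix + name, val)
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix + name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=ad.get_default_dtype())
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """Kaiming-normal initialization suited to ReLU stacks."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """Stride-1 square-kernel convolution with same or valid padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 dilation: int = 1, same_pad: bool = True, zero_init: bool = False):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.dilation = dilation
        self.pad = dilation * (kernel - 1) // 2 if same_pad else 0
        fan_in = in_ch * kernel * kernel
        w = np.zeros((out_ch, in_ch, kernel, kernel)) if zero_init else \
            he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, pad=self.pad, dilation=self.dilation)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        self.weight = Tensor(he_init(rng, (out_f, in_f), in_f), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ad.linear(x, self.weight, self.bias)


class Adam:
    """Adaptive-moment estimation with bias correction."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else g
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * gd * gd
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state(self) -> dict:
        return {"t": self.t, "lr": self.lr,
                "m": [a.copy() for a in self.m], "v": [a.copy() for a in self.v]}

    def load_state(self, st: dict) -> None:
        self.t = int(st["t"])
        self.lr = float(st["lr"])
        self.m = [np.asarray(a, dtype=np.float64).copy() for a in st["m"]]
        self.v = [np.asarray(a, dtype=np.float64).copy() for a in st["v"]]
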