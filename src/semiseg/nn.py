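"""Neural-network building blocks (modules, layers, softmax) on top of
:mod:`semiseg.autograd`."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Module", "Conv2d", "Linear", "ConvBlock", "softmax", "log_softmax"]

# networks train in float32 (memory-bandwidth bound on CPU); the loss and
# metric code paths stay in whatever dtype the caller supplies
PARAM_DTYPE = np.float32


class Module:
    """Base class with PyTorch-style named parameter traversal."""

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, val in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(val, Tensor):
                out.append((full, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(full))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}"))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"parameter name mismatch: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data[...] = state[k]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """2-D convolution with He-normal initialisation."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 padding: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        w = (rng.standard_normal((out_ch, in_ch, kernel, kernel)) * scale)
        self.weight = Tensor(w.astype(PARAM_DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=PARAM_DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)

    def set_identity(self) -> None:
        """Make this a channel-preserving identity map (1x1 kernels only)."""
        co, ci, kh, kw = self.weight.shape
        if co != ci or kh != 1 or kw != 1:
            raise ValueError("identity init requires a square-channel 1x1 convolution")
        self.weight.data[...] = np.eye(co, dtype=self.weight.data.dtype).reshape(co, ci, 1, 1)
        self.bias.data[...] = 0.0


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(1.0 / in_f)
        w = rng.standard_normal((in_f, out_f)) * scale
        self.weight = Tensor(w.astype(PARAM_DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, dtype=PARAM_DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ConvBlock(Module):
    """Two 3x3 conv + ReLU layers, the standard UNet stage."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None):
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng=rng)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).relu()).relu()


def softmax(logits: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable softmax along ``axis`` (class axis by default)."""
    shifted = logits - logits.max_const(axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(logits: Tensor, axis: int = 1) -> Tensor:
    shifted = logits - logits.max_const(axis=axis, keepdims=True)
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()
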