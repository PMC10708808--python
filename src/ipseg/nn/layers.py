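"""Module containers and learned layers for the NumPy network stack."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .autograd import Tensor

__all__ = ["Module", "Conv2d", "Conv1d", "BatchNorm1d", "BatchNorm2d",
           "Sequential", "he_init"]


def he_init(rng: np.random.Generator, shape, fan_in: int, gain: float = 1.0,
            dtype=np.float32) -> np.ndarray:
    """Fan-in-scaled normal initialization (He et al. style)."""
    std = gain * np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Module:
    """Tiny nn.Module analogue: tracks parameters, buffers and train mode."""

    def __init__(self):
        self.training = True

    # ------------------------------------------------------------ traversal
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def _own_tensors(self):
        for name, value in vars(self).items():
            if isinstance(value, Tensor):
                yield name, value

    def _own_buffers(self):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield name, value

    def named_parameters(self, prefix: str = ""):
        for name, t in self._own_tensors():
            if t.requires_grad:
                yield prefix + name, t
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [t for _, t in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # ---------------------------------------------------------- state dicts
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, t in self._own_tensors():
            out[prefix + name] = t.data
        for name, buf in self._own_buffers():
            out[prefix + name] = buf
        for cname, child in self._children():
            out.update(child.state_dict(prefix + cname + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, t in self._own_tensors():
            t.data = np.array(state[prefix + name], dtype=t.data.dtype)
        for name, buf in self._own_buffers():
            src = state[prefix + name]
            np.copyto(buf, np.asarray(src, dtype=buf.dtype))
        for cname, child in self._children():
            child.load_state_dict(state, prefix + cname + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size, rng: np.random.Generator,
                 *, stride=1, padding=0, dilation=1, bias: bool = True,
                 gain: float = 1.0):
        super().__init__()
        kh, kw = kernel_size if isinstance(kernel_size, tuple) else (kernel_size,) * 2
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = in_ch * kh * kw
        self.weight = Tensor(he_init(rng, (out_ch, in_ch, kh, kw), fan_in, gain),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class Conv1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 rng: np.random.Generator, *, padding=0, bias: bool = True,
                 gain: float = 1.0):
        super().__init__()
        self.padding = padding
        fan_in = in_ch * kernel_size
        self.weight = Tensor(he_init(rng, (out_ch, in_ch, kernel_size), fan_in, gain),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv1d(x, self.weight, self.bias, padding=self.padding)


class _BatchNorm(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, training=self.training,
                            momentum=self.momentum, eps=self.eps)


class BatchNorm1d(_BatchNorm):
    """Channel-axis normalization for (N, C, L) tensors."""


class BatchNorm2d(_BatchNorm):
    """Channel-axis normalization for (N, C, H, W) tensors."""


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.steps = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.steps:
            x = m(x)
        return x
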