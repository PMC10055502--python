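"""Parameterised layers built on the autodiff core."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: recursive parameter collection and flat state dicts."""

    def named_parameters(self, prefix=""):
        out = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(full + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
        return out

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self):
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=p.data.dtype).copy()

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    """Same-padded stride-1 convolution with optional bias."""

    def __init__(self, c_in, c_out, kernel, rng, bias=True):
        kh, kw = kernel
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel dims must be odd for same padding")
        fan_in = c_in * kh * kw
        self.weight = Tensor(_he_init(rng, (c_out, c_in, kh, kw), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32),
                           requires_grad=True) if bias else None

    def __call__(self, x):
        return ag.conv2d(x, self.weight, self.bias)


class Dense(Module):
    def __init__(self, d_in, d_out, rng):
        self.weight = Tensor(_he_init(rng, (d_in, d_out), d_in), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return ag.matmul(x, self.weight) + self.bias


class ConvBlock(Module):
    """Two same-padded convolutions, each followed by ReLU."""

    def __init__(self, c_in, c_out, kernel, rng):
        self.conv1 = Conv2d(c_in, c_out, kernel, rng)
        self.conv2 = Conv2d(c_out, c_out, kernel, rng)

    def __call__(self, x):
        return ag.relu(self.conv2(ag.relu(self.conv1(x))))


class AttentionGate(Module):
    """Additive attention gate on a skip connection.

    The gating signal ``g`` comes from the coarser decoder level (already
    upsampled to the skip's resolution); the skip features are multiplied by
    a per-pixel sigmoid coefficient.
    """

    def __init__(self, c_skip, c_gate, c_int, rng):
        self.w_x = Conv2d(c_skip, c_int, (1, 1), rng, bias=False)
        self.w_g = Conv2d(c_gate, c_int, (1, 1), rng, bias=True)
        self.psi = Conv2d(c_int, 1, (1, 1), rng, bias=True)

    def __call__(self, skip, gate):
        a = ag.relu(self.w_x(skip) + self.w_g(gate))
        coeff = ag.sigmoid(self.psi(a))
        return ag.mul(skip, coeff)
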