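"""Layer primitives (modules with learnable parameters) on the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    """A tensor that is optimized; always requires grad."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Tiny module base: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def modules(self):
        out = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self):
        """Flatten all parameters and buffers to {path: array}."""
        state = {}

        def walk(mod, prefix):
            for k, v in mod.__dict__.items():
                if isinstance(v, Parameter):
                    state[prefix + k] = v.data.copy()
                elif isinstance(v, np.ndarray):
                    state[prefix + k] = v.copy()
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")

        walk(self, "")
        return state

    def load_state_dict(self, state):
        def walk(mod, prefix):
            for k, v in mod.__dict__.items():
                if isinstance(v, Parameter):
                    v.data = state[prefix + k].astype(v.data.dtype).copy()
                elif isinstance(v, np.ndarray):
                    mod.__dict__[k] = state[prefix + k].copy()
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")

        walk(self, "")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    """Stride-1 same-padded convolution, He-initialized."""

    def __init__(self, in_ch, out_ch, kernel=3, rng=None, bias=True):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias)


class ConvTranspose2x2(Module):
    """2x2 stride-2 transposed convolution (spatial doubling)."""

    def __init__(self, in_ch, out_ch, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_init(rng, (in_ch, out_ch, 2, 2), in_ch * 4))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x):
        return ag.conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics for eval mode.

    The normalization itself is expressed in engine primitives, so its
    gradient comes out of the tape rather than a hand-derived formula.
    """

    def __init__(self, num_ch, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones((1, num_ch, 1, 1)))
        self.beta = Parameter(np.zeros((1, num_ch, 1, 1)))
        self.running_mean = np.zeros((1, num_ch, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, num_ch, 1, 1), dtype=np.float32)

    def forward(self, x):
        if self.training:
            mu = ag.tmean(x, axis=(0, 2, 3), keepdims=True)
            var = ag.tmean(ag.pow_scalar(x - mu, 2.0), axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.astype(np.float32)
            self.running_var = (1 - m) * self.running_var + m * var.data.astype(np.float32)
            inv = ag.pow_scalar(ag.add_scalar(var, self.eps), -0.5)
            xhat = (x - mu) * inv
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - Tensor(self.running_mean)) * Tensor(inv)
        return xhat * self.gamma + self.beta


class Linear(Module):
    def __init__(self, in_f, out_f, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_init(rng, (in_f, out_f), in_f))
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x):
        return ag.matmul(x, self.weight) + self.bias


class Adam:
    """Adaptive-moment optimizer with per-step bias correction."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
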