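"""Layers, parameter management and SGD, built on :mod:`amsmlp.autodiff`.

Initialization conventions: fully connected weights are truncated-normal
(std 0.02, clipped at two standard deviations), convolution weights are
He-normal, biases zero, normalization scales one / shifts zero. Every layer
draws from the ``numpy.random.Generator`` passed at construction, so a model
built twice from the same seed has bitwise-identical weights.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def trunc_normal(rng, shape, std=0.02):
    v = rng.standard_normal(shape) * std
    return np.clip(v, -2.0 * std, 2.0 * std).astype(np.float32)


def he_normal(rng, shape, fan_in):
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: tracks parameters, buffers and sub-modules by attribute."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value):
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    def parameters(self):
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_state(self, prefix=""):
        for k, p in self._params.items():
            yield prefix + k, p.data
        for k, b in self._buffers.items():
            yield prefix + k, b
        for k, m in self._modules.items():
            yield from m.named_state(prefix + k + ".")

    def state_dict(self):
        return {k: v.copy() for k, v in self.named_state()}

    def load_state_dict(self, state):
        own = dict(self.named_state())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        for k, arr in own.items():
            arr[...] = state[k]

    def train(self, mode=True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self):
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    """Dense map along one axis of an N-D tensor (default: last)."""

    def __init__(self, in_features, out_features, rng, axis=-1, bias=True):
        super().__init__()
        self.axis = axis
        self.weight = Parameter(trunc_normal(rng, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def __call__(self, x):
        return ad.linear(x, self.weight, self.bias, axis=self.axis)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, rng, padding=None, bias=True):
        super().__init__()
        self.padding = padding
        self.weight = Parameter(
            he_normal(rng, (out_ch, in_ch, kernel, kernel), in_ch * kernel * kernel)
        )
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def __call__(self, x):
        return ad.conv2d(x, self.weight, self.bias, padding=self.padding)


class ConvTranspose2x(Module):
    """Kernel-2, stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.weight = Parameter(he_normal(rng, (in_ch, out_ch, 2, 2), in_ch * 4))
        self.bias = Parameter(np.zeros(out_ch))

    def __call__(self, x):
        return ad.deconv2x(x, self.weight, self.bias)


class BatchNorm(Module):
    """Batch normalization; ``axes`` are the reduction axes (per-feature)."""

    def __init__(self, num_features, axes=(0, 2, 3), momentum=0.1, eps=1e-5):
        super().__init__()
        self.axes = tuple(axes)
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def __call__(self, x):
        return ad.batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.axes, self.training, self.momentum, self.eps,
        )


class LayerNorm(Module):
    """Layer normalization over one axis (default: channel axis of NCHW)."""

    def __init__(self, num_features, axis=1, eps=1e-5):
        super().__init__()
        self.axis = axis
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))

    def __call__(self, x):
        return ad.layer_norm(x, self.gamma, self.beta, self.axis, self.eps)


class ConvBNReLU(Module):
    """3x3 (or 1x1) convolution + batch norm + ReLU, the encoder/decoder brick."""

    def __init__(self, in_ch, out_ch, rng, kernel=3):
        super().__init__()
        # bias omitted: batch norm absorbs any constant shift
        self.conv = Conv2d(in_ch, out_ch, kernel, rng, bias=False)
        self.bn = BatchNorm(out_ch)

    def __call__(self, x):
        return self.bn(self.conv(x)).relu()


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, m):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self):
        return {"velocity": [v.copy() for v in self.velocity], "lr": self.lr}

    def load_state_dict(self, state):
        for v, s in zip(self.velocity, state["velocity"]):
            v[...] = s
        self.lr = float(state["lr"])


def poly_lr(base_lr, step, total_steps, power=0.9):
    """Polynomial decay schedule used for the full training run."""
    frac = 1.0 - step / max(1, total_steps)
    return base_lr * max(frac, 0.0) ** power
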