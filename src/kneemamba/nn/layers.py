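"""Layer/module abstractions over the autodiff engine.

Modules own named parameters (and non-trainable buffers), recurse through
child modules, and can dump/load a flat state dict of NumPy arrays.  All
initialisation draws from an explicit `numpy.random.Generator` so a model
built twice from the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

DTYPE = np.float32


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(value, dtype=DTYPE), requires_grad=True)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=DTYPE)
        self._buffers[name] = arr
        object.__setattr__(self, name, arr)
        return arr

    # -- traversal ----------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield prefix + n, p
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix + mn + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialisation ------------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + n: p.data.copy() for n, p in self._params.items()}
        out.update({prefix + n: b.copy() for n, b in self._buffers.items()})
        for mn, m in self._modules.items():
            out.update(m.state_dict(prefix + mn + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for n in self._params:
            self._params[n].data = np.asarray(state[prefix + n], dtype=DTYPE).copy()
        for n in self._buffers:
            arr = np.asarray(state[prefix + n], dtype=DTYPE)
            self._buffers[n][...] = arr
        for mn, m in self._modules.items():
            m.load_state_dict(state, prefix + mn + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.register_parameter("weight", _kaiming(rng, (d_in, d_out), d_in))
        self.bias = None
        if bias:
            self.register_parameter("bias", np.zeros(d_out))

    def forward(self, x: Tensor) -> Tensor:
        y = ag.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: int | None = None, bias: bool = True):
        super().__init__()
        k = kernel_size
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.register_parameter(
            "weight", _kaiming(rng, (c_out, c_in, k, k), c_in * k * k))
        self.bias = None
        if bias:
            self.register_parameter("bias", np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.register_parameter("gamma", np.ones(channels))
        self.register_parameter("beta", np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))

    def forward(self, x: Tensor) -> Tensor:
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean[...] = ((1 - self.momentum) * self.running_mean
                                      + self.momentum * mu)
            self.running_var[...] = ((1 - self.momentum) * self.running_var
                                     + self.momentum * var)
            return ag.normalize(x, g, b, axes=(0, 2, 3), eps=self.eps)
        mu = Tensor(self.running_mean[None, :, None, None])
        var = Tensor(self.running_var[None, :, None, None])
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * g + b


class LayerNorm(Module):
    """Normalises over the trailing feature axis (token layout ..., C)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.register_parameter("gamma", np.ones(dim))
        self.register_parameter("beta", np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        return ag.normalize(x, self.gamma, self.beta, axes=(-1,), eps=self.eps)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class AdamW:
    """Decoupled weight-decay Adam (beta1 is the 'momentum' knob)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.weight_decay:
                p.data = p.data * (1.0 - self.lr * self.weight_decay)
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
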