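"""Neural-network module system: layers, containers, initialization.

Mirrors the familiar ``Module`` idiom: submodules and parameters are
registered through attribute assignment, ``parameters()`` walks the tree,
``train()``/``eval()`` toggle batch-norm behaviour.  Initialization is
Kaiming-uniform for convolutions/linears and unit-gamma/zero-beta for
norms, drawn from a module-level generator that :func:`seed_all` reseeds so
model construction is reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "seed_all", "Parameter", "Module", "Sequential", "ModuleList",
    "Conv2d", "Linear", "BatchNorm2d", "LayerNorm", "MaxPool2d", "Upsample",
    "SiLU", "ReLU", "Sigmoid", "Identity",
]

_RNG = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Reseed the generator used for parameter initialization."""
    global _RNG
    _RNG = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
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
        elif isinstance(value, Tensor):
            self._buffers[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value: Tensor):
        value.requires_grad = False
        setattr(self, name, value)

    def named_parameters(self, prefix=""):
        for k, p in self._params.items():
            yield (f"{prefix}{k}", p)
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{k}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix=""):
        for k, b in self._buffers.items():
            yield (f"{prefix}{k}", b)
        for k, m in self._modules.items():
            yield from m.named_buffers(prefix=f"{prefix}{k}.")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        """Number of trainable scalars in the module tree."""
        return sum(p.size for p in self.parameters())

    def state_dict(self):
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({name: b.data for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        own.update(dict(self.named_buffers()))
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)[:5]}...")
        for name, arr in state.items():
            if name in own:
                if own[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}: {own[name].data.shape} vs {arr.shape}")
                own[name].data = np.asarray(arr, dtype=np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._seq = []
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
            self._seq.append(m)

    def __iter__(self):
        return iter(self._seq)

    def __getitem__(self, i):
        return self._seq[i]

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def forward(self, *a):  # containers have no forward of their own
        raise NotImplementedError


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel, stride=1, padding=0, bias=True):
        super().__init__()
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.kernel, self.stride, self.padding = int(kernel), int(stride), int(padding)
        fan_in = self.c_in * self.kernel * self.kernel
        bound = math.sqrt(6.0 / fan_in)  # Kaiming uniform, gain for linear-ish activations
        self.weight = Parameter(_RNG.uniform(-bound, bound, (self.c_out, self.c_in, self.kernel, self.kernel)))
        if bias:
            b = 1.0 / math.sqrt(fan_in)
            self.bias = Parameter(_RNG.uniform(-b, b, (self.c_out,)))
        else:
            self.bias = None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, d_in, d_out, bias=True):
        super().__init__()
        bound = math.sqrt(6.0 / d_in)
        self.weight = Parameter(_RNG.uniform(-bound, bound, (d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out, dtype=np.float32)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    # eps/momentum follow the YOLO ecosystem convention (1e-3, 0.03)
    def __init__(self, channels, eps=1e-3, momentum=0.03):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_mean", Tensor(np.zeros(channels, dtype=np.float32)))
        self.register_buffer("running_var", Tensor(np.ones(channels, dtype=np.float32)))

    def forward(self, x):
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean.data = ((1 - self.momentum) * self.running_mean.data
                                      + self.momentum * mu.data.reshape(c))
            self.running_var.data = ((1 - self.momentum) * self.running_var.data
                                     + self.momentum * var.data.reshape(c))
        else:
            mu = Tensor(self.running_mean.data.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.data.reshape(1, c, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        w = self.weight.reshape(1, c, 1, 1)
        b = self.bias.reshape(1, c, 1, 1)
        return xhat * w + b


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.weight + self.bias


class MaxPool2d(Module):
    def __init__(self, kernel, stride=None, padding=0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride or kernel, padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel, self.stride, self.padding)


class Upsample(Module):
    def __init__(self, factor=2):
        super().__init__()
        self.factor = factor

    def forward(self, x):
        return F.upsample_nearest(x, self.factor)


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Identity(Module):
    def forward(self, x):
        return x
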